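"""Scoring inferred isoform sets against a ground truth.

Inferred and true isoforms (binary exon compositions over a shared gene
model) are paired by a maximum-cardinality, minimum-weight matching under
Hamming distance, solved as a rectangular assignment problem in O(I^3).
A matched pair at distance d <= p*E is a p-partial true positive; unmatched
inferred isoforms are false positives and truths not covered by a p-TP are
false negatives.  p = 0 reproduces exact matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .gene_io import GeneModel


def hamming(a, b) -> int:
    """Number of mismatched exons between two compositions."""
    a, b = tuple(a), tuple(b)
    if len(a) != len(b):
        raise ValueError(f"composition lengths differ: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class MatchingResult:
    inferred: list[tuple[int, ...]]
    truth: list[tuple[int, ...]]
    distance: np.ndarray            # |inferred| x |truth| Hamming distances
    pairs: list[tuple[int, int]]    # (inferred index, truth index), max cardinality
    objective: int                  # sum of matched distances M

    @property
    def unmatched_inferred(self) -> list[int]:
        used = {k for k, _ in self.pairs}
        return [k for k in range(len(self.inferred)) if k not in used]

    @property
    def unmatched_truth(self) -> list[int]:
        used = {l for _, l in self.pairs}
        return [l for l in range(len(self.truth)) if l not in used]


def match_isoforms(inferred, truth) -> MatchingResult:
    """Maximum-cardinality minimum-weight matching of inferred to true isoforms.

    Unequal set sizes are handled by leaving the excess side unmatched (the
    rectangular assignment matches all of the smaller side), which restores
    the maximum-cardinality semantics of the square formulation.  Ties among
    equal-weight matchings are broken deterministically by sorting both sets
    lexicographically before solving.
    """
    inferred = sorted(tuple(c) for c in inferred)
    truth = sorted(tuple(c) for c in truth)
    if inferred and truth:
        E = len(inferred[0])
        if any(len(c) != E for c in inferred + truth):
            raise ValueError("all compositions must share one exon count E")
    if not inferred or not truth:
        d = np.zeros((len(inferred), len(truth)), dtype=int)
        return MatchingResult(inferred, truth, d, [], 0)
    d = np.array([[hamming(a, b) for b in truth] for a in inferred], dtype=int)
    rows, cols = linear_sum_assignment(d)
    pairs = sorted(zip(rows.tolist(), cols.tolist()))
    return MatchingResult(inferred, truth, d, pairs, int(d[rows, cols].sum()))


def precision_recall(
    result: MatchingResult, p: float, E: int
) -> tuple[float | None, float | None]:
    """p-partial precision and recall from a matching (Hamming <= p*E is a TP).

    Unmatched inferred isoforms count as false positives at every threshold;
    truths not covered by a p-TP are false negatives.  Undefined quantities
    (no predictions, or no truths) are returned as None.
    """
    if not 0 <= p <= 1:
        raise ValueError("threshold p must lie in [0, 1]")
    cutoff = p * E
    tp = sum(1 for k, l in result.pairs if result.distance[k, l] <= cutoff)
    fp = len(result.inferred) - tp
    fn = len(result.truth) - tp
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    return precision, recall


def base_coverage(result: MatchingResult, gene: GeneModel) -> float:
    """Length-weighted fraction of true isoform bases covered by matched partners.

    For each matched pair, the covered bases are those of exons present in
    both the true and inferred compositions; the aggregate is total covered
    bases over total true bases (coverage, not precision: a superset of the
    truth scores 1).
    """
    lengths = gene.exon_lengths()
    covered = total = 0
    for k, l in result.pairs:
        t = result.truth[l]
        a = result.inferred[k]
        total += sum(int(lengths[i]) for i in range(gene.E) if t[i])
        covered += sum(int(lengths[i]) for i in range(gene.E) if t[i] and a[i])
    return covered / total if total else 1.0
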