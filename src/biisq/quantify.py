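"""Per-sample transcript read allocation, RPKM, and transcript ratios.

Reads mapped to a gene are allocated to its transcripts by the fitted
per-sample isoform proportions; expression is reported as
RPKM_t = 1e9 * X_t / (L_t * N) with L_t the summed length of the
transcript's included exons and N the sample's total of retained mapped
reads.  A transcript's ratio is its share of the gene's allocated reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gene_io import GeneModel
from .model_core import Isoform


def allocate_reads(gene_read_total: float, psi_row: np.ndarray) -> np.ndarray:
    """X_t = gene total x psi_t; conservation is exact."""
    psi_row = np.asarray(psi_row, dtype=float)
    if gene_read_total < 0:
        raise ValueError("gene_read_total must be >= 0")
    if psi_row.ndim != 1 or abs(psi_row.sum() - 1.0) > 1e-6 or (psi_row < 0).any():
        raise ValueError("psi_row must be a simplex")
    return gene_read_total * psi_row


def rpkm(X_t: float, L_t: float, N: float) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if L_t <= 0 or N <= 0:
        raise ValueError("L_t and N must be strictly positive")
    return 1e9 * X_t / (L_t * N)


def transcript_length(gene: GeneModel, iso: Isoform) -> int:
    """bp of the isoform's included exons under the half-open convention."""
    return gene.transcript_length(iso.exon_chain())


def transcript_ratios(X_t: np.ndarray) -> np.ndarray:
    """ratio_t = X_t / sum(X_t); all-zero genes yield NaN (flagged missing)."""
    X_t = np.asarray(X_t, dtype=float)
    total = X_t.sum()
    if total == 0:
        return np.full(X_t.shape, np.nan)
    return X_t / total


@dataclass
class QuantResult:
    """Tidy per gene/transcript/sample quantification table."""

    table: pd.DataFrame  # gene_id, transcript_code, sample_id, X_t, L_t, RPKM, ratio

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def quantify_samples(
    gene: GeneModel,
    isoforms: list[Isoform],
    psi: np.ndarray,
    gene_read_totals: np.ndarray,
    library_sizes: np.ndarray,
    sample_ids: list[str] | None = None,
) -> QuantResult:
    """Allocate reads and compute RPKM/ratios for every sample and transcript.

    ``psi`` is m x K per-sample proportions; ``gene_read_totals`` the retained
    reads mapped to this gene per sample; ``library_sizes`` the per-sample
    totals N of retained mapped reads.
    """
    psi = np.asarray(psi, dtype=float)
    m, K = psi.shape
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(m)]
    lengths = np.array([transcript_length(gene, iso) for iso in isoforms])
    rows = []
    for j in range(m):
        X_t = allocate_reads(float(gene_read_totals[j]), psi[j])
        ratios = transcript_ratios(X_t)
        for k, iso in enumerate(isoforms):
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "transcript_code": iso.code,
                    "sample_id": sample_ids[j],
                    "X_t": X_t[k],
                    "L_t": int(lengths[k]),
                    "RPKM": rpkm(X_t[k], lengths[k], float(library_sizes[j])),
                    "ratio": ratios[k],
                }
            )
    return QuantResult(pd.DataFrame(rows))
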