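"""Gene models, read terms, and the read-term count matrix.

A gene is modelled as an ordered list of non-overlapping exonic intervals in
transcription (5'->3') order.  Mapped reads are summarised as *read terms*:
tuples ``(start, end, exon_set)`` giving the terminal base-pair positions of
the read and the set of exons it covers.  Per-sample read-term counts form
the V x m observation matrix consumed by the model.

Coordinates are half-open (end-exclusive) throughout: a 100 bp read starting
at position 40 of a gene whose first two exons are [1,67) and [2617,2865)
covers 27 bases of exon 1 and 73 bases of exon 2 and yields the term
``(40, 2690, {1,2})``.  Exon indices are 1-based and transcription-ordered;
minus-strand genes are converted to transcription order at model-build time.
"""

from __future__ import annotations

import bisect
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    GeneNotFoundError,
    MalformedAnnotationError,
    MixedGeneError,
    ReadTruncationError,
    UnmappableReadError,
)

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """Transcription model of one gene: ordered, non-overlapping exons.

    ``exons`` are half-open genomic intervals in transcription order
    (exon 1 is 5'-most).  On the minus strand the list is therefore in
    descending genomic order and bases within each exon are walked from the
    high coordinate down.
    """

    gene_id: str
    exons: tuple[tuple[int, int], ...]
    strand: str = "+"
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if len(self.exons) < 1:
            raise MalformedAnnotationError(f"gene {self.gene_id!r} has no exons")
        if self.strand not in "+-":
            raise MalformedAnnotationError(f"bad strand {self.strand!r}")
        ivs = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if e1 > s2:
                raise MalformedAnnotationError(
                    f"gene {self.gene_id!r}: overlapping exons {(s1, e1)} and {(s2, e2)}"
                )
        for s, e in ivs:
            if e <= s:
                raise MalformedAnnotationError(f"empty exon interval {(s, e)}")
        expected = tuple(ivs) if self.strand == "+" else tuple(ivs[::-1])
        if self.exons != expected:
            object.__setattr__(self, "exons", expected)

    @property
    def E(self) -> int:
        return len(self.exons)

    def exon_lengths(self, chain: Sequence[int] | None = None) -> np.ndarray:
        idx = range(1, self.E + 1) if chain is None else chain
        return np.array([self.exons[i - 1][1] - self.exons[i - 1][0] for i in idx])

    def transcript_length(self, chain: Sequence[int] | None = None) -> int:
        return int(self.exon_lengths(chain).sum())

    # -- transcript-coordinate mapping over an exon chain -------------------

    def _offsets(self, chain: Sequence[int]) -> list[int]:
        offs, total = [], 0
        for i in chain:
            offs.append(total)
            total += self.exons[i - 1][1] - self.exons[i - 1][0]
        offs.append(total)
        return offs

    def genomic_to_transcript(self, pos: int, chain: Sequence[int] | None = None) -> int:
        """Index of genomic base ``pos`` within the concatenated exonic sequence."""
        chain = list(chain) if chain is not None else list(range(1, self.E + 1))
        offs = self._offsets(chain)
        for off, i in zip(offs, chain):
            s, e = self.exons[i - 1]
            if s <= pos < e:
                return off + (pos - s if self.strand == "+" else e - 1 - pos)
        raise UnmappableReadError(
            f"position {pos} is intronic or outside gene {self.gene_id!r}"
        )

    def transcript_to_genomic(self, tpos: int, chain: Sequence[int] | None = None) -> int:
        chain = list(chain) if chain is not None else list(range(1, self.E + 1))
        offs = self._offsets(chain)
        if not 0 <= tpos < offs[-1]:
            raise ReadTruncationError(f"transcript position {tpos} out of range")
        j = bisect.bisect_right(offs, tpos) - 1
        s, e = self.exons[chain[j] - 1]
        within = tpos - offs[j]
        return s + within if self.strand == "+" else e - 1 - within


@dataclass(frozen=True)
class ReadTerm:
    """(start, end, exon_set) summary of one mapped read.

    ``start`` is the genomic coordinate of the 5'-most base, ``end`` is one
    past the 3'-most base in transcription direction, and ``exon_set`` lists
    the covered exon indices (1-based, strictly increasing).
    """

    start: int
    end: int
    exon_set: tuple[int, ...]
    gene_id: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if len(self.exon_set) == 0:
            raise UnmappableReadError("read term covers no exon")
        if any(b <= a for a, b in zip(self.exon_set, self.exon_set[1:])):
            raise UnmappableReadError(f"exon_set {self.exon_set} not strictly increasing")


@dataclass
class ReadTermMatrix:
    """V x m nonnegative integer counts over a shared read-term catalog."""

    catalog: list[ReadTerm]
    X: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.int64)
        if self.X.shape != (len(self.catalog), len(self.sample_ids)):
            raise ValueError(
                f"X shape {self.X.shape} != (V={len(self.catalog)}, m={len(self.sample_ids)})"
            )
        if (self.X < 0).any():
            raise ValueError("negative read-term counts")

    @property
    def V(self) -> int:
        return len(self.catalog)

    @property
    def m(self) -> int:
        return len(self.sample_ids)

    def column_totals(self) -> np.ndarray:
        return self.X.sum(axis=0)

    # -- TSV round trip ------------------------------------------------------

    def to_tsv(self, path) -> None:
        rows = {
            "term_index": np.arange(self.V),
            "start": [t.start for t in self.catalog],
            "end": [t.end for t in self.catalog],
            "exons": [",".join(map(str, t.exon_set)) for t in self.catalog],
        }
        df = pd.DataFrame(rows)
        for j, sid in enumerate(self.sample_ids):
            df[sid] = self.X[:, j]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, gene_id: str | None = None) -> "ReadTermMatrix":
        df = pd.read_csv(path, sep="\t")
        meta = ["term_index", "start", "end", "exons"]
        sample_ids = [c for c in df.columns if c not in meta]
        catalog = [
            ReadTerm(int(r.start), int(r.end),
                     tuple(int(x) for x in str(r.exons).split(",")), gene_id)
            for r in df.itertuples()
        ]
        X = df[sample_ids].to_numpy(dtype=np.int64)
        return cls(catalog, X, sample_ids)


# ---------------------------------------------------------------------------
# Annotation parsing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptRecord:
    """One annotated transcript: half-open genomic exon intervals."""

    gene_id: str
    transcript_id: str
    exons: tuple[tuple[int, int], ...]
    strand: str = "+"
    chrom: str = "chr1"
    basic: bool = True


def _merge_intervals(ivs: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    ivs = sorted(ivs)
    out: list[list[int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return tuple((s, e) for s, e in out)


def build_gene_model(
    annotation_records: Iterable[TranscriptRecord], gene_id: str
) -> GeneModel:
    """Select the representative transcript of ``gene_id`` and build its model.

    Representative selection mirrors standard annotation practice: transcripts
    flagged "basic" are preferred; among candidates the transcript with the
    most exons wins.  When several candidates tie on exon count, their exons
    are pooled and overlapping intervals collapsed into a standard exon set.
    """
    records = [r for r in annotation_records if r.gene_id == gene_id]
    if not records:
        raise GeneNotFoundError(gene_id)
    for r in records:
        if len(r.exons) == 0:
            raise MalformedAnnotationError(
                f"transcript {r.transcript_id!r} of gene {gene_id!r} has no exons"
            )
    basic = [r for r in records if r.basic]
    candidates = basic if basic else records
    top = max(len(r.exons) for r in candidates)
    winners = [r for r in candidates if len(r.exons) == top]
    pooled: list[tuple[int, int]] = [iv for r in winners for iv in r.exons]
    exons = _merge_intervals(pooled)
    return GeneModel(gene_id, exons, winners[0].strand, winners[0].chrom)


def gene_model_from_gff(gff_path: str, gene_id: str) -> GeneModel:
    """Parse a GFF3/GTF file (GENCODE dialect accepted) into a GeneModel."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique",
        keep_order=True, disable_infer_genes=True, disable_infer_transcripts=True,
    )
    records = []
    for tr in db.features_of_type(("transcript", "mRNA")):
        gid = tr.attributes.get("gene_id", [tr.attributes.get("Parent", [""])[0]])[0]
        if gid != gene_id:
            continue
        exons = tuple(
            sorted((ex.start - 1, ex.end) for ex in db.children(tr, featuretype="exon"))
        )
        tags = tr.attributes.get("tag", [])
        records.append(
            TranscriptRecord(gid, tr.id, exons, tr.strand, tr.seqid,
                             basic=("basic" in tags) or not tags)
        )
    return build_gene_model(records, gene_id)


# ---------------------------------------------------------------------------
# Read -> read term
# ---------------------------------------------------------------------------


def read_to_term(
    read_start: int,
    read_length: int,
    gene: GeneModel,
    chain: Sequence[int] | None = None,
) -> ReadTerm:
    """Walk ``read_length`` exonic bases 5'->3' from ``read_start``.

    ``chain`` restricts the walk to a subset of exons in transcription order
    (the exon chain of the source isoform); by default all exons of the gene
    are walked.  Introns are skipped; a start inside an intron raises
    :class:`UnmappableReadError` and a read overrunning the last chained exon
    raises :class:`ReadTruncationError`.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    chain = list(chain) if chain is not None else list(range(1, gene.E + 1))
    t0 = gene.genomic_to_transcript(read_start, chain)
    t_end = t0 + read_length
    offs = gene._offsets(chain)
    if t_end > offs[-1]:
        raise ReadTruncationError(
            f"read at {read_start} (+{read_length} bp) overruns the exon chain"
        )
    covered = tuple(
        i for j, i in enumerate(chain) if offs[j] < t_end and offs[j + 1] > t0
    )
    last = gene.transcript_to_genomic(t_end - 1, chain)
    end = last + 1 if gene.strand == "+" else last - 1
    return ReadTerm(read_start, end, covered, gene.gene_id)


def term_from_blocks(
    blocks: Sequence[tuple[int, int]], gene: GeneModel
) -> ReadTerm:
    """Build a term from the aligned reference blocks of a (spliced) read.

    Every aligned base must be exonic; reads hanging into introns are
    unmappable under the gene model.
    """
    blocks = _merge_intervals(blocks)
    length = sum(e - s for s, e in blocks)
    covered = []
    for i in range(1, gene.E + 1):
        s, e = gene.exons[i - 1]
        for bs, be in blocks:
            lo, hi = max(s, bs), min(e, be)
            if lo < hi:
                covered.append(i)
                break
    exonic = sum(
        max(0, min(e, be) - max(s, bs))
        for s, e in gene.exons
        for bs, be in blocks
    )
    if exonic != length:
        raise UnmappableReadError("aligned blocks extend outside the exon model")
    tpos = [gene.genomic_to_transcript(p, None) for b in blocks for p in (b[0], b[1] - 1)]
    start = gene.transcript_to_genomic(min(tpos))
    last = gene.transcript_to_genomic(max(tpos))
    end = last + 1 if gene.strand == "+" else last - 1
    return ReadTerm(start, end, tuple(covered), gene.gene_id)


def terms_from_alignments(sam_path: str, gene: GeneModel) -> list[ReadTerm]:
    """Convert primary, QC-passing alignments in a SAM/BAM file to read terms.

    Unmapped, secondary, supplementary, duplicate and QC-fail records are
    excluded; reads inconsistent with the exon model (intronic bases) are
    skipped.  Each aligned segment yields one term.
    """
    import pysam

    terms: list[ReadTerm] = []
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for rec in fh:
            if (rec.is_unmapped or rec.is_secondary or rec.is_supplementary
                    or rec.is_duplicate or rec.is_qcfail):
                continue
            blocks = rec.get_blocks()
            if not blocks:
                continue
            try:
                terms.append(term_from_blocks(blocks, gene))
            except UnmappableReadError:
                continue
    return terms


# ---------------------------------------------------------------------------
# Catalog construction and reduction
# ---------------------------------------------------------------------------


def build_count_matrix(
    per_sample_terms: Mapping[str, Iterable[ReadTerm]]
) -> ReadTermMatrix:
    """Union catalog across samples; ``x_vj`` = multiplicity of term v in sample j."""
    sample_ids = list(per_sample_terms)
    counters = {sid: Counter(per_sample_terms[sid]) for sid in sample_ids}
    genes = {t.gene_id for c in counters.values() for t in c if t.gene_id is not None}
    if len(genes) > 1:
        raise MixedGeneError(f"terms reference multiple genes: {sorted(genes)}")
    catalog = sorted(
        {t for c in counters.values() for t in c},
        key=lambda t: (t.exon_set, t.start, t.end),
    )
    X = np.zeros((len(catalog), len(sample_ids)), dtype=np.int64)
    for j, sid in enumerate(sample_ids):
        for v, t in enumerate(catalog):
            X[v, j] = counters[sid].get(t, 0)
    return ReadTermMatrix(catalog, X, sample_ids)


def _collapse_with_width(matrix: ReadTermMatrix, width: int) -> ReadTermMatrix:
    groups: dict[tuple, list[int]] = {}
    for v, t in enumerate(matrix.catalog):
        key = (t.exon_set, t.start // width)
        groups.setdefault(key, []).append(v)
    catalog, rows = [], []
    for key in sorted(groups):
        members = groups[key]
        # representative start = count-weighted mode of member starts
        weight: Counter = Counter()
        for v in members:
            weight[matrix.catalog[v].start] += int(matrix.X[v].sum())
        mode = min(weight, key=lambda s: (-weight[s], s))
        at_mode = [v for v in members if matrix.catalog[v].start == mode]
        best = min(at_mode, key=lambda v: (-matrix.X[v].sum(), matrix.catalog[v].end))
        catalog.append(matrix.catalog[best])
        rows.append(matrix.X[members].sum(axis=0))
    return ReadTermMatrix(catalog, np.array(rows, dtype=np.int64), matrix.sample_ids)


def _n_bins(matrix: ReadTermMatrix, width: int) -> int:
    return len({(t.exon_set, t.start // width) for t in matrix.catalog})


def reduce_catalog(matrix: ReadTermMatrix, target: int) -> ReadTermMatrix:
    """Collapse terms with identical exon sets and nearby starts toward ``target``.

    Start positions are binned per exon set at a fixed width chosen by
    bisection so the resulting catalog size lands nearest ``target``; the
    grand total of counts is conserved exactly and terms with different exon
    sets are never merged.  A catalog already at or under ``target`` is
    returned unchanged.
    """
    if target < 1:
        raise ValueError("target must be >= 1")
    if matrix.V <= target:
        return matrix
    lo, hi = 1, max(t.start for t in matrix.catalog) + 1
    if _n_bins(matrix, lo) <= target:
        return _collapse_with_width(matrix, lo)
    while lo < hi:  # smallest width with n_bins <= target (n_bins non-increasing)
        mid = (lo + hi) // 2
        if _n_bins(matrix, mid) <= target:
            hi = mid
        else:
            lo = mid + 1
    candidates = [lo] if lo == 1 else [lo - 1, lo]
    best = min(candidates, key=lambda w: (abs(_n_bins(matrix, w) - target), w))
    return _collapse_with_width(matrix, best)


# ---------------------------------------------------------------------------
# Isoform-set GTF round trip (shared by simulate / fit output / evaluate)
# ---------------------------------------------------------------------------


def write_isoform_gtf(gene: GeneModel, compositions: Iterable[Sequence[int]], path) -> None:
    """Write one GTF transcript (with exon features) per composition vector."""
    lines = []
    for n, comp in enumerate(compositions):
        tid = f"{gene.gene_id}.iso{n + 1}"
        incl = [gene.exons[i] for i, c in enumerate(comp) if c]
        lo = min(s for s, _ in incl)
        hi = max(e for _, e in incl)
        attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tid}";'
        lines.append(
            f"{gene.chrom}\tbiisq\ttranscript\t{lo + 1}\t{hi}\t.\t{gene.strand}\t.\t{attrs}"
        )
        for s, e in sorted(incl):
            lines.append(
                f"{gene.chrom}\tbiisq\texon\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t{attrs}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_isoform_gtf(path, gene: GeneModel) -> list[tuple[int, ...]]:
    """Read compositions back from a GTF, snapping exons to the gene model.

    An annotated exon overlapping any part of a reference exon marks that
    exon as included (partial overlap counts as reconstructing the exon).
    """
    per_tid: dict[str, set[int]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "exon":
                continue
            attrs = f[8]
            tid = attrs.split('transcript_id "', 1)[1].split('"', 1)[0]
            s, e = int(f[3]) - 1, int(f[4])
            if tid not in per_tid:
                per_tid[tid] = set()
                order.append(tid)
            for i in range(1, gene.E + 1):
                xs, xe = gene.exons[i - 1]
                if max(xs, s) < min(xe, e):
                    per_tid[tid].add(i)
    comps = []
    for tid in order:
        comp = tuple(1 if i in per_tid[tid] else 0 for i in range(1, gene.E + 1))
        comps.append(comp)
    return comps
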