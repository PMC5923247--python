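"""Desk-scale synthetic RNA-seq data with exported ground truth.

Two generators are provided.  ``simulate_gene_reads`` emulates multi-sample
short-read simulations over a gene model: per-sample isoform proportions are
drawn from a symmetric Dirichlet (concentration 1 by default), read starts
follow a 5'-biased distribution over each isoform's exonic coordinates, and
genes whose realised reads miss the coverage target or leave an exon
uncovered are resampled.  ``fragment_long_reads`` turns long (Iso-Seq-style)
alignments into short reads separated by normally distributed inserts
(mean 10 bp, sd 40 bp, truncated at zero) until a target fraction of the
transcript is covered, preserving the source positions so that mapping
biases carry over.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InvalidIsoformError
from .gene_io import GeneModel, ReadTerm, read_to_term
from .model_core import Isoform

logger = logging.getLogger(__name__)

# BEERS parameter grid exposed as presets for scaled-down replicas
BEERS_NOVEL_TRANSCRIPTS = (2, 4, 6, 12, 16)
BEERS_COVERAGES = (1, 5, 15, 50, 100)


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Short-read gene simulation settings.

    ``coverage`` is the per-sample target depth over the gene's exonic bases;
    ``bias`` controls the 5' start-position bias (0 = uniform starts);
    ``alpha`` is the per-sample Dirichlet concentration (1 = the symmetric
    Dirichlet used throughout).
    """

    n_isoforms: int = 2
    m: int = 20
    coverage: float = 15.0
    read_length: int = 50
    alpha: float = 1.0
    bias: float = 0.0
    seed: int = 0
    max_attempts: int = 50

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.read_length < 1:
            raise ValueError("read length must be >= 1")
        if self.n_isoforms < 1:
            raise ValueError("need at least one true isoform")


@dataclass
class FragmentConfig:
    """Long-read fragmentation settings (insert ~ Normal(10, 40^2), bp)."""

    read_length: int = 100
    span: float = 1.0
    insert_mean: float = 10.0
    insert_sd: float = 40.0
    paired: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.span <= 1:
            raise ValueError("span must lie in (0, 1]")
        if self.read_length < 1:
            raise ValueError("read length must be >= 1")


@dataclass
class SimulatedRead:
    """One simulated read with its genomic start and source isoform chain."""

    name: str
    sample: str
    start: int            # genomic coordinate of the 5'-most base
    length: int
    chain: tuple[int, ...]  # exon chain of the source isoform

    def to_term(self, gene: GeneModel) -> ReadTerm:
        return read_to_term(self.start, self.length, gene, self.chain)


@dataclass
class SimTruth:
    isoforms: list[Isoform]
    psi: np.ndarray          # m x K latent proportions
    z_counts: np.ndarray     # m x K realised reads per isoform
    sample_ids: list[str]
    attempts: int = 1


# ---------------------------------------------------------------------------
# 5'-biased start positions
# ---------------------------------------------------------------------------


def start_weights(n_positions: int, bias: float) -> np.ndarray:
    """Unnormalised start-position weights over transcript-relative positions.

    Positive ``bias`` weights positions by a Gamma density with shape
    1/(1+bias) evaluated at the relative position, concentrating starts
    toward the 5' end; ``bias`` = 0 falls back to the uniform distribution.
    """
    if n_positions < 1:
        raise ValueError("need at least one admissible start position")
    if bias == 0:
        return np.full(n_positions, 1.0 / n_positions)
    u = (np.arange(n_positions) + 0.5) / n_positions
    w = stats.gamma.pdf(u, a=1.0 / (1.0 + bias), scale=1.0)
    return w / w.sum()


# ---------------------------------------------------------------------------
# BEERS-style gene simulation
# ---------------------------------------------------------------------------


def random_isoforms(gene: GeneModel, n: int, read_length: int, rng) -> list[Isoform]:
    """Draw ``n`` distinct compositions long enough to carry a read."""
    seen: set[tuple[int, ...]] = set()
    out: list[Isoform] = []
    for _ in range(1000):
        comp = tuple(int(b) for b in (rng.random(gene.E) < 0.5))
        if not any(comp) or comp in seen:
            continue
        iso = Isoform(comp)
        if gene.transcript_length(iso.exon_chain()) < read_length:
            continue
        seen.add(comp)
        out.append(iso)
        if len(out) == n:
            return out
    raise InvalidIsoformError(
        f"could not draw {n} distinct isoforms of length >= {read_length} bp"
    )


def _draw_sample_reads(
    gene: GeneModel,
    isoforms: Sequence[Isoform],
    psi_row: np.ndarray,
    n_reads: int,
    cfg: SimConfig,
    sample_id: str,
    rng,
) -> tuple[list[SimulatedRead], np.ndarray]:
    reads: list[SimulatedRead] = []
    z_counts = np.zeros(len(isoforms), dtype=np.int64)
    chains = [iso.exon_chain() for iso in isoforms]
    starts_per_iso = [
        gene.transcript_length(ch) - cfg.read_length + 1 for ch in chains
    ]
    weights = [start_weights(n, cfg.bias) for n in starts_per_iso]
    z = rng.choice(len(isoforms), size=n_reads, p=psi_row)
    for i, k in enumerate(z):
        z_counts[k] += 1
        t0 = rng.choice(starts_per_iso[k], p=weights[k])
        g0 = gene.transcript_to_genomic(int(t0), chains[k])
        reads.append(
            SimulatedRead(f"{sample_id}.r{i}", sample_id, g0, cfg.read_length, chains[k])
        )
    return reads, z_counts


def simulate_gene_reads(
    gene: GeneModel, cfg: SimConfig, isoforms: Sequence[Isoform] | None = None
) -> tuple[list[SimulatedRead], SimTruth]:
    """Simulate per-sample short reads for one gene plus the latent truth.

    Per sample: proportions ~ Dirichlet(alpha, ..., alpha) over the true
    isoforms; per read: isoform ~ proportions, start from the 5'-biased
    distribution over that isoform's exonic coordinates.  Realisations whose
    pooled reads fall under the coverage target or leave some exon of some
    true isoform without a read are discarded and resampled (logged).
    """
    rng = np.random.default_rng(cfg.seed)
    if isoforms is None:
        isoforms = random_isoforms(gene, cfg.n_isoforms, cfg.read_length, rng)
    isoforms = list(isoforms)
    for iso in isoforms:
        if gene.transcript_length(iso.exon_chain()) < cfg.read_length:
            raise InvalidIsoformError(
                f"isoform {iso.composition} shorter than the read length"
            )
    exonic = gene.transcript_length()
    n_reads = max(1, int(np.ceil(cfg.coverage * exonic / cfg.read_length)))
    sample_ids = [f"s{j}" for j in range(cfg.m)]
    needed_exons = {i for iso in isoforms for i in iso.exon_chain()}
    for attempt in range(1, cfg.max_attempts + 1):
        psi = rng.dirichlet(np.full(len(isoforms), cfg.alpha), size=cfg.m)
        all_reads: list[SimulatedRead] = []
        z_counts = np.zeros((cfg.m, len(isoforms)), dtype=np.int64)
        for j, sid in enumerate(sample_ids):
            reads, zc = _draw_sample_reads(
                gene, isoforms, psi[j], n_reads, cfg, sid, rng
            )
            all_reads.extend(reads)
            z_counts[j] = zc
        covered: set[int] = set()
        for r in all_reads:
            covered.update(r.to_term(gene).exon_set)
        depth = len(all_reads) * cfg.read_length / (exonic * cfg.m)
        if needed_exons <= covered and depth >= cfg.coverage * 0.999:
            return all_reads, SimTruth(isoforms, psi, z_counts, sample_ids, attempt)
        logger.info(
            "resampling gene %s (attempt %d): coverage %.2f, uncovered exons %s",
            gene.gene_id, attempt, depth, sorted(needed_exons - covered),
        )
    raise RuntimeError(f"gene {gene.gene_id!r} failed filters after {cfg.max_attempts} attempts")


# ---------------------------------------------------------------------------
# ISSRS-style fragmentation of long reads
# ---------------------------------------------------------------------------


@dataclass
class LongRead:
    """A long aligned read: genomic start plus its exon chain and length."""

    name: str
    start: int
    length: int
    chain: tuple[int, ...] | None = None  # default: all exons of the gene


def sample_inserts(n: int, cfg: FragmentConfig, rng=None) -> np.ndarray:
    """Pre-truncation insert-size draws ~ Normal(insert_mean, insert_sd^2)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    return rng.normal(cfg.insert_mean, cfg.insert_sd, size=n)


def fragment_long_reads(
    long_reads: Sequence[LongRead],
    gene: GeneModel,
    cfg: FragmentConfig,
) -> tuple[list[SimulatedRead], np.ndarray]:
    """Fragment long reads into short reads until the span target is met.

    Short reads are emitted along each long read separated by inserts drawn
    from Normal(10, 40^2) truncated at >= 0 (negative draws abut the reads);
    passes restart from the 5' end at a jittered offset until the covered
    fraction of the long read reaches ``cfg.span``.  Positions are copied
    from the source read so mapping biases persist.  Returns the short reads
    and the pre-truncation insert draws (whose sample mean/sd retain the
    printed 10/40 bp).  Long reads shorter than the short-read length are
    skipped with a warning.
    """
    rng = np.random.default_rng(cfg.seed)
    out: list[SimulatedRead] = []
    raw_inserts: list[float] = []
    for lr in long_reads:
        if lr.length < cfg.read_length:
            logger.warning("long read %s shorter than %d bp; skipped", lr.name, cfg.read_length)
            continue
        chain = lr.chain if lr.chain is not None else tuple(range(1, gene.E + 1))
        t_start = gene.genomic_to_transcript(lr.start, chain)
        covered = np.zeros(lr.length, dtype=bool)
        n_emitted = 0
        guard = 0
        while covered.mean() < cfg.span and guard < 10000:
            offset = 0 if n_emitted == 0 else int(rng.integers(0, cfg.read_length))
            pos = offset
            while pos + cfg.read_length <= lr.length:
                guard += 1
                if not covered[pos:pos + cfg.read_length].all():
                    g0 = gene.transcript_to_genomic(t_start + pos, chain)
                    out.append(
                        SimulatedRead(
                            f"{lr.name}.f{n_emitted}", lr.name, g0,
                            cfg.read_length, tuple(chain),
                        )
                    )
                    covered[pos:pos + cfg.read_length] = True
                    n_emitted += 1
                draw = float(rng.normal(cfg.insert_mean, cfg.insert_sd))
                raw_inserts.append(draw)
                pos += cfg.read_length + max(0, int(round(draw)))
                if covered.mean() >= cfg.span:
                    break
    return out, np.asarray(raw_inserts)


# ---------------------------------------------------------------------------
# SAM export (minimal mandatory columns)
# ---------------------------------------------------------------------------


def reads_to_sam(
    reads: Sequence[SimulatedRead], gene: GeneModel, path
) -> None:
    """Write simulated reads as spliced single-end SAM records via pysam."""
    import pysam

    ref_len = max(e for _, e in gene.exons) + 1
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"},
         "SQ": [{"SN": gene.chrom, "LN": int(ref_len)}]}
    )
    segs = []
    for r in reads:
        term = r.to_term(gene)
        blocks = _term_blocks(term, r.length, gene, r.chain)
        a = pysam.AlignedSegment(header)
        a.query_name = r.name
        a.flag = 0 if gene.strand == "+" else 16
        a.reference_id = 0
        a.reference_start = blocks[0][0]
        a.mapping_quality = 60
        cig = []
        prev_end = None
        for bs, be in blocks:
            if prev_end is not None and bs > prev_end:
                cig.append((3, bs - prev_end))       # N: skipped intron
            cig.append((0, be - bs))                 # M
            prev_end = be
        a.cigartuples = cig
        a.query_sequence = "A" * r.length
        segs.append(a)
    segs.sort(key=lambda a: a.reference_start)
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for a in segs:
            fh.write(a)


def _term_blocks(
    term: ReadTerm, length: int, gene: GeneModel, chain: Sequence[int]
) -> list[tuple[int, int]]:
    """Genomic (start, end) blocks of a read term, ascending order."""
    chain = list(chain)
    t0 = gene.genomic_to_transcript(term.start, chain)
    blocks = []
    offs = gene._offsets(chain)
    for j, i in enumerate(chain):
        lo, hi = max(offs[j], t0), min(offs[j + 1], t0 + length)
        if lo < hi:
            a = gene.transcript_to_genomic(lo, chain)
            b = gene.transcript_to_genomic(hi - 1, chain)
            blocks.append((min(a, b), max(a, b) + 1))
    return sorted(blocks)
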