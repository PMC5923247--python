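"""The biisq generative model.

Each gene is treated independently.  An isoform is a binary exon-composition
vector over the gene's E transcription-ordered exons, encoded as an integer
by reading the 5'->3' composition as a binary numeral (exon 1 = most
significant bit), so (1,0,1) <-> 5 for a three-exon gene.

The hierarchy couples samples through a two-level Dirichlet process: a global
DP over the countable isoform catalog (uniform base distribution over binary
encodings, concentration omega) and a per-sample DP with base G0 and
concentration alpha.  Read terms are emitted per isoform from a Dirichlet
whose parameters are masked by the binary usage vector b_k (b_kv ~
Bernoulli(pi_iota) where iota is the exon in which term v starts); a small
noise floor epsilon keeps every emission Dirichlet well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.special import betaln

from .errors import InvalidIsoformError, InvalidStateError
from .gene_io import GeneModel, ReadTerm, ReadTermMatrix, read_to_term

# ---------------------------------------------------------------------------
# Isoform encoding
# ---------------------------------------------------------------------------


def encode_isoform(composition: Sequence[int]) -> int:
    """Read the 5'->3' composition as an MSB-first binary numeral."""
    comp = tuple(int(c) for c in composition)
    if len(comp) < 1 or any(c not in (0, 1) for c in comp):
        raise InvalidIsoformError(f"bad composition {composition!r}")
    if not any(comp):
        raise InvalidIsoformError("isoform includes no exon")
    code = 0
    for c in comp:
        code = (code << 1) | c
    return code


def decode_isoform(code: int, E: int) -> tuple[int, ...]:
    if not 1 <= code < (1 << E):
        raise InvalidIsoformError(f"code {code} out of range for E={E}")
    return tuple((code >> (E - 1 - i)) & 1 for i in range(E))


@dataclass(frozen=True)
class Isoform:
    composition: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "composition", tuple(int(c) for c in self.composition))
        encode_isoform(self.composition)  # validates

    @property
    def code(self) -> int:
        return encode_isoform(self.composition)

    @property
    def E(self) -> int:
        return len(self.composition)

    def exon_chain(self) -> tuple[int, ...]:
        return tuple(i + 1 for i, c in enumerate(self.composition) if c)


def compatibility(term: ReadTerm, iso: Isoform) -> bool:
    """Junction consistency of a read term with an isoform.

    True iff every exon the term covers is included in the isoform and every
    exon strictly between consecutive covered exons is excluded (the read's
    junctions assert those skips).
    """
    comp = iso.composition
    if term.exon_set[-1] > len(comp):
        raise InvalidIsoformError("term exon index exceeds composition length")
    for i in term.exon_set:
        if not comp[i - 1]:
            return False
    for a, b in zip(term.exon_set, term.exon_set[1:]):
        for mid in range(a + 1, b):
            if comp[mid - 1]:
                return False
    return True


# ---------------------------------------------------------------------------
# Hyperparameters and states
# ---------------------------------------------------------------------------


@dataclass
class Hyperparameters:
    """Model hyperparameters; symmetric defaults, all configurable.

    omega/alpha: global and per-sample DP concentrations; r, s: beta prior
    shapes for per-exon inclusion probabilities pi; eta: emission Dirichlet
    base weights (scalar broadcast over terms); eps: emission noise floor;
    K_max/L_max: truncation levels for inference.
    """

    omega: float = 1.0
    alpha: float = 1.0
    r: float = 1.0
    s: float = 1.0
    eta: float = 1.0
    eps: float = 1e-3
    K_max: int = 20
    L_max: int = 10

    def __post_init__(self) -> None:
        for name in ("omega", "alpha", "r", "s", "eta", "eps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.K_max >= self.L_max >= 1:
            raise ValueError("require K_max >= L_max >= 1")

    @classmethod
    def from_config(cls, path) -> "Hyperparameters":
        """Load from a flat key=value file; unknown keys are rejected."""
        kwargs = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, val = (x.strip() for x in line.split("=", 1))
                if key in ("K_max", "L_max"):
                    kwargs[key] = int(val)
                else:
                    kwargs[key] = float(val)
        return cls(**kwargs)


def emission_simplex(
    iso: Isoform, catalog: Sequence[ReadTerm], eps: float = 1e-3,
    eta: float | np.ndarray = 1.0,
) -> np.ndarray:
    """Dirichlet-mean emission probabilities of ``iso`` over the term catalog.

    Mass is spread over compatible terms in proportion to eta and an additive
    floor eps/V is folded into every term before renormalising, so each of
    the V terms retains strictly positive probability.
    """
    V = len(catalog)
    eta_vec = np.broadcast_to(np.asarray(eta, dtype=float), (V,))
    b = np.array([compatibility(t, iso) for t in catalog], dtype=float)
    raw = b * eta_vec
    if raw.sum() > 0:
        raw = raw / raw.sum()
    else:  # no compatible term: fall back to the floor alone
        raw = np.zeros(V)
    return (raw + eps / V) / (1.0 + eps if raw.sum() > 0 else eps)


@dataclass
class GlobalState:
    """Point configuration of the global level: catalog, usage, weights."""

    isoforms: list[Isoform]
    pi: np.ndarray                      # length-E exon inclusion probabilities
    global_weights: np.ndarray          # length-K simplex (stick-broken G0)

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.global_weights = np.asarray(self.global_weights, dtype=float)
        if abs(self.global_weights.sum() - 1.0) > 1e-6:
            raise InvalidStateError("global weights do not sum to 1")

    @property
    def K(self) -> int:
        return len(self.isoforms)

    def usage_matrix(self, catalog: Sequence[ReadTerm]) -> np.ndarray:
        """K x V binary b, zero outside terms compatible with each isoform."""
        return np.array(
            [[compatibility(t, iso) for t in catalog] for iso in self.isoforms],
            dtype=float,
        )

    def emissions(self, catalog: Sequence[ReadTerm], hyp: Hyperparameters) -> np.ndarray:
        return np.stack(
            [emission_simplex(iso, catalog, hyp.eps, hyp.eta) for iso in self.isoforms]
        )


@dataclass
class SampleState:
    """Per-sample slots: proportions psi (m x L), slot->isoform map c (m x L)."""

    psi: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=float)
        self.c = np.asarray(self.c, dtype=int)
        if self.psi.shape != self.c.shape:
            raise InvalidStateError("psi and c shapes differ")
        if np.abs(self.psi.sum(axis=1) - 1.0).max() > 1e-6:
            raise InvalidStateError("a psi row is not a simplex")

    @property
    def m(self) -> int:
        return self.psi.shape[0]

    @property
    def L(self) -> int:
        return self.psi.shape[1]


# ---------------------------------------------------------------------------
# Exact log joint (z marginalised analytically)
# ---------------------------------------------------------------------------


def _stick_log_prior(weights: np.ndarray, conc: float) -> float:
    """Log density of a finite simplex under truncated Beta(1, conc) sticks."""
    remaining = 1.0
    total = 0.0
    for wk in weights[:-1]:
        frac = np.clip(wk / max(remaining, 1e-300), 1e-12, 1 - 1e-12)
        total += stats.beta.logpdf(frac, 1.0, conc) - np.log(max(remaining, 1e-300))
        remaining -= wk
    return float(total)


def log_likelihood(
    X: ReadTermMatrix,
    global_state: GlobalState,
    samples: SampleState,
    hyp: Hyperparameters,
) -> float:
    """Log p(X | psi, c, catalog): reads i.i.d., isoform assignment summed out.

    Each read-term occurrence in sample j contributes
    log sum_l psi_jl * beta_{c_jl, v}.
    """
    beta = global_state.emissions(X.catalog, hyp)       # K x V
    ll = 0.0
    for j in range(samples.m):
        mix = samples.psi[j] @ beta[samples.c[j]]       # length V
        counts = X.X[:, j]
        nz = counts > 0
        ll += float(counts[nz] @ np.log(mix[nz]))
    return ll


def log_joint(
    X: ReadTermMatrix,
    global_state: GlobalState,
    samples: SampleState,
    hyp: Hyperparameters,
) -> float:
    """Exact log of prior(pi, b, sticks, psi, c) x likelihood(X | states)."""
    if samples.c.max(initial=0) >= global_state.K:
        raise InvalidStateError("c maps to an isoform outside the catalog")
    lp = 0.0
    # pi_iota ~ Beta(r, s)
    pi = np.clip(global_state.pi, 1e-12, 1 - 1e-12)
    lp += float(np.sum((hyp.r - 1) * np.log(pi) + (hyp.s - 1) * np.log(1 - pi)
                       - betaln(hyp.r, hyp.s)))
    # b_kv ~ Bernoulli(pi_iota(v)), iota(v) = exon in which term v starts
    b = global_state.usage_matrix(X.catalog)
    iota = np.array([t.exon_set[0] - 1 for t in X.catalog])
    pv = pi[iota]
    lp += float(np.sum(b * np.log(pv) + (1 - b) * np.log(1 - pv)))
    # global and per-sample stick-breaking priors
    lp += _stick_log_prior(global_state.global_weights, hyp.omega)
    for j in range(samples.m):
        lp += _stick_log_prior(samples.psi[j], hyp.alpha)
        lp += float(np.sum(np.log(global_state.global_weights[samples.c[j]])))
    return lp + log_likelihood(X, global_state, samples, hyp)


# ---------------------------------------------------------------------------
# Sampling from the generative model
# ---------------------------------------------------------------------------


def candidate_terms(
    gene: GeneModel,
    isoforms: Iterable[Isoform],
    read_length: int,
    stride: int = 10,
) -> list[ReadTerm]:
    """Union of read terms of ``read_length`` at strided starts over each isoform."""
    seen: dict[ReadTerm, None] = {}
    for iso in isoforms:
        chain = iso.exon_chain()
        tlen = gene.transcript_length(chain)
        if tlen < read_length:
            raise InvalidIsoformError(
                f"isoform {iso.composition} shorter than read length {read_length}"
            )
        starts = list(range(0, tlen - read_length + 1, stride))
        if starts[-1] != tlen - read_length:
            starts.append(tlen - read_length)
        for t0 in starts:
            g0 = gene.transcript_to_genomic(t0, chain)
            term = read_to_term(g0, read_length, gene, chain)
            seen.setdefault(term)
    return sorted(seen, key=lambda t: (t.exon_set, t.start, t.end))


def sample_dataset(
    gene: GeneModel,
    true_isoforms: Sequence[Isoform],
    hyp: Hyperparameters,
    m: int,
    reads_per_sample: int,
    seed: int,
    global_weights: np.ndarray | None = None,
    read_length: int = 50,
    stride: int = 10,
) -> tuple[ReadTermMatrix, dict]:
    """Draw a model-generated data set plus its latent truth record.

    Per-sample proportions follow Dirichlet(alpha * K * global_weights), i.e.
    the symmetric Dirichlet(1,...,1) at the defaults; each read picks an
    isoform from the sample's proportions and a term from that isoform's
    epsilon-floored compatible-term simplex.  The truth record carries the
    latent proportions, the realised per-isoform read counts, and the catalog.
    """
    if len(true_isoforms) == 0:
        raise InvalidIsoformError("need at least one true isoform")
    rng = np.random.default_rng(seed)
    K = len(true_isoforms)
    if global_weights is None:
        global_weights = np.full(K, 1.0 / K)
    global_weights = np.asarray(global_weights, dtype=float)
    catalog = candidate_terms(gene, true_isoforms, read_length, stride)
    beta = np.stack([emission_simplex(iso, catalog, hyp.eps, hyp.eta)
                     for iso in true_isoforms])
    conc = hyp.alpha * K * global_weights
    psi = rng.dirichlet(conc, size=m)
    X = np.zeros((len(catalog), m), dtype=np.int64)
    z_counts = np.zeros((m, K), dtype=np.int64)
    for j in range(m):
        if reads_per_sample == 0:
            continue
        z = rng.choice(K, size=reads_per_sample, p=psi[j])
        for k in range(K):
            nk = int((z == k).sum())
            z_counts[j, k] = nk
            if nk:
                X[:, j] += rng.multinomial(nk, beta[k])
    matrix = ReadTermMatrix(list(catalog), X, [f"s{j}" for j in range(m)])
    truth = {
        "isoforms": list(true_isoforms),
        "psi": psi,
        "z_counts": z_counts,
        "global_weights": global_weights,
        "catalog": list(catalog),
        "read_length": read_length,
    }
    return matrix, truth
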