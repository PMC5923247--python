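"""Stochastic variational inference with merge-propose-reduce catalog moves.

The posterior over the two-level Dirichlet-process hierarchy is approximated
with a truncated variational family: Dirichlet factors for per-isoform
emissions, beta factors for global and per-sample sticks, and categorical
responsibilities for the slot-to-isoform map c and the read-to-slot
assignments z.  Each iteration updates the local factors of a random
minibatch of samples and takes a Robbins-Monro natural-gradient step on the
global factors with step size rho_t = (t + delay)^(-forgetting).

The discrete isoform catalog is handled outside the gradient updates by
three moves executed every ``move_period`` iterations, in order:

* merge  — for every isoform pair, compare the plug-in data likelihood
  before and after pooling the pair's mass under the better member's
  composition (proportions re-optimised after the pooling); accept when
  the likelihood does not drop, so duplicate slots collapse on ties.
* propose — build candidate isoforms from the exon unions of randomly
  sampled, poorly mapped read terms (best mapping responsibility < 0.5);
  any novel composition enlarges the catalog and all variational
  parameters are reinitialised.
* reduce — drop isoforms to which no read maps with probability > 0.01,
  never removing the last one.

``fit`` runs several independently seeded restarts and returns the one with
the best maximum-a-posteriori plug-in score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma

from .errors import DegenerateDataError
from .gene_io import GeneModel, ReadTermMatrix
from .model_core import Hyperparameters, Isoform, compatibility

# ---------------------------------------------------------------------------
# Configuration and state
# ---------------------------------------------------------------------------


@dataclass
class FitConfig:
    """SVI schedule, move cadence and thresholds.

    forgetting/delay parametrise the step sizes rho_t = (t+delay)^-forgetting;
    ``minibatch`` samples are used per stochastic update; catalog moves run
    every ``move_period`` iterations; ``poor_map_threshold`` flags read terms
    for proposals and ``reduce_threshold`` prunes unsupported isoforms.
    """

    forgetting: float = 0.6
    delay: float = 1.0
    minibatch: int = 16
    move_period: int = 30
    poor_map_threshold: float = 0.5
    reduce_threshold: float = 0.01
    tol: float = 1e-5
    max_iter: int = 1000
    restarts: int = 5
    seed: int = 0
    inner_iters: int = 10
    check_every: int = 5
    max_proposals: int = 3
    merge_polish_iters: int = 10

    def __post_init__(self) -> None:
        if self.move_period < 1:
            raise ValueError("move_period must be >= 1")
        for name in ("poor_map_threshold", "reduce_threshold"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass
class VariationalState:
    """Variational posterior snapshot for one gene.

    ``lam`` are emission Dirichlet parameters (K x V), ``u``/``v`` the global
    stick betas, ``phi`` the slot-to-isoform responsibilities (m x L x K),
    ``resp`` the marginal read-to-isoform responsibilities (m x V x K), and
    ``p`` the per-sample isoform proportions implied by the fit (m x K).
    """

    catalog: list[Isoform]
    lam: np.ndarray
    u: np.ndarray
    v: np.ndarray
    hyp: Hyperparameters
    config: FitConfig
    phi: np.ndarray | None = None
    resp: np.ndarray | None = None
    p: np.ndarray | None = None
    iteration: int = 0
    trace: list = field(default_factory=list)
    moves_log: list = field(default_factory=list)
    converged: bool = False
    loglik: float = -np.inf
    score: float = -np.inf
    _prior_key: tuple = field(default=(), repr=False)
    _prior: np.ndarray | None = field(default=None, repr=False)

    @property
    def K(self) -> int:
        return len(self.catalog)

    def beta_bar(self) -> np.ndarray:
        return self.lam / self.lam.sum(axis=1, keepdims=True)

    def compositions(self) -> list[tuple[int, ...]]:
        return [iso.composition for iso in self.catalog]


# ---------------------------------------------------------------------------
# Expectations and local updates
# ---------------------------------------------------------------------------


def _elog_dirichlet(lam: np.ndarray) -> np.ndarray:
    return digamma(lam) - digamma(lam.sum(axis=-1, keepdims=True))


def _elog_sticks(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """E[log weights] under Beta(a, b) stick fractions."""
    elog_frac = digamma(a) - digamma(a + b)
    elog_rest = digamma(b) - digamma(a + b)
    out = elog_frac.copy()
    out[..., 1:] += np.cumsum(elog_rest[..., :-1], axis=-1)
    return out


def _stick_means(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    frac = a / (a + b)
    rest = np.cumprod(1 - frac[..., :-1], axis=-1)
    out = frac.copy()
    out[..., 1:] *= rest
    out /= out.sum(axis=-1, keepdims=True)
    return out


def _softmax(scores: np.ndarray, axis: int) -> np.ndarray:
    scores = scores - scores.max(axis=axis, keepdims=True)
    w = np.exp(scores)
    return w / w.sum(axis=axis, keepdims=True)


def _local_step(
    Xb: np.ndarray,
    elog_beta: np.ndarray,
    elog_sigma: np.ndarray,
    hyp: Hyperparameters,
    inner_iters: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Coordinate-ascent local update for a batch of samples.

    Xb is V x B counts; returns (zeta, phi, a, b): read-to-slot
    responsibilities (B,V,L), slot-to-isoform responsibilities (B,L,K) and
    the per-sample stick betas (B,L).
    """
    V, B = Xb.shape
    K = elog_beta.shape[0]
    L = min(hyp.L_max, max(K, 1))
    XbT = Xb.T  # B x V
    phi = np.full((B, L, K), 1.0 / K)
    a = np.ones((B, L))
    b = np.full((B, L), hyp.alpha)
    zeta = np.full((B, V, L), 1.0 / L)
    for _ in range(inner_iters):
        elog_psi = _elog_sticks(a, b)                                  # B x L
        scores = elog_psi[:, None, :] + np.einsum(
            "blk,kv->bvl", phi, elog_beta, optimize=True
        )
        zeta = _softmax(scores, axis=2)
        weighted = XbT[:, :, None] * zeta                              # B x V x L
        phi_scores = elog_sigma[None, None, :] + np.einsum(
            "bvl,kv->blk", weighted, elog_beta, optimize=True
        )
        phi = _softmax(phi_scores, axis=2)
        n_l = weighted.sum(axis=1)                                     # B x L
        a = 1.0 + n_l
        tail = np.cumsum(n_l[:, ::-1], axis=1)[:, ::-1] - n_l
        b = hyp.alpha + tail
    return zeta, phi, a, b


def _mixture_from_local(
    phi: np.ndarray, a: np.ndarray, b: np.ndarray
) -> np.ndarray:
    """Per-sample isoform proportions p implied by local factors."""
    psi = _stick_means(a, b)
    p = np.einsum("bl,blk->bk", psi, phi, optimize=True)
    p = np.clip(p, 1e-12, None)
    return p / p.sum(axis=1, keepdims=True)


def _model_beta(state: VariationalState, X: ReadTermMatrix) -> np.ndarray:
    """Deterministic model emissions per catalog entry: the Dirichlet-mean
    simplex over compatible terms with the eps floor folded in."""
    prior = _get_prior(state, X)
    b = (prior > state.hyp.eta * state.hyp.eps * 1.5).astype(float)
    raw = b / np.maximum(b.sum(axis=1, keepdims=True), 1.0)
    eps = state.hyp.eps
    return (raw + eps / X.V) / (1.0 + eps)


def _plugin_mixture(state: VariationalState, X: ReadTermMatrix):
    """Full-data local pass -> (p, beta, resp, phi, loglik).

    p[j, k] is sample j's posterior proportion of isoform k, obtained from
    the truncated local factors and sharpened by mixture-weight EM under the
    model emissions (the compositions themselves are the hypotheses being
    scored, so move decisions use the model's emission simplexes rather than
    the fitted ones); resp[j, v, k] is the probability that a read of term v
    in sample j arose from isoform k.
    """
    beta = _model_beta(state, X)
    elog_beta = _elog_dirichlet(state.lam)
    elog_sigma = _elog_sticks(state.u, state.v)
    zeta, phi, a, b = _local_step(
        X.X, elog_beta, elog_sigma, state.hyp, state.config.inner_iters
    )
    p = _mixture_from_local(phi, a, b)
    # polish from the variational weights and from uniform weights and keep
    # the better optimum: redundant compositions create flat directions in
    # the mixture likelihood where a single start can park
    p1 = _em_polish(p, beta, X, 100)
    p2 = _em_polish(np.full_like(p, 1.0 / p.shape[1]), beta, X, 100)
    ll1, ll2 = _loglik_from(p1, beta, X), _loglik_from(p2, beta, X)
    p, ll = (p1, ll1) if ll1 >= ll2 else (p2, ll2)
    resp = p[:, None, :] * beta.T[None, :, :]                          # m x V x K
    resp /= resp.sum(axis=2, keepdims=True)
    return p, beta, resp, phi, ll


def _loglik_from(p: np.ndarray, beta: np.ndarray, X: ReadTermMatrix) -> float:
    mix = np.clip(p @ beta, 1e-300, None)
    return float((X.X.T * np.log(mix)).sum())


def _em_polish(
    p: np.ndarray, beta: np.ndarray, X: ReadTermMatrix, iters: int
) -> np.ndarray:
    """A few EM steps on the per-sample mixture weights (monotone in loglik)."""
    totals = np.maximum(X.X.sum(axis=0)[:, None], 1)
    for _ in range(iters):
        mix = np.clip(p @ beta, 1e-300, None)
        p = p * ((X.X.T / mix) @ beta.T) / totals
        p = np.clip(p, 1e-12, None)
        p /= p.sum(axis=1, keepdims=True)
    return p


def _catalog_log_prior(state: VariationalState, E: int) -> float:
    """Uniform base-measure prior over binary isoform codes (MAP penalty on K)."""
    return -state.K * E * np.log(2.0)


# ---------------------------------------------------------------------------
# Initialisation
# ---------------------------------------------------------------------------


def _span_composition(exon_set: tuple[int, ...], E: int) -> tuple[int, ...]:
    """Composition spanning the exon set: 1 on [min,max] minus skipped exons."""
    comp = [0] * E
    for i in range(exon_set[0], exon_set[-1] + 1):
        comp[i - 1] = 1
    for lo, hi in zip(exon_set, exon_set[1:]):
        for mid in range(lo + 1, hi):
            comp[mid - 1] = 0
    return tuple(comp)


def _initial_catalog(X: ReadTermMatrix, E: int, K_max: int) -> list[Isoform]:
    """One junction-consistent isoform per observed exon-set span (most
    supported spans first) plus the full-length isoform, capped at K_max."""
    totals: dict[tuple[int, ...], int] = {}
    for v, term in enumerate(X.catalog):
        totals[term.exon_set] = totals.get(term.exon_set, 0) + int(X.X[v].sum())
    comps: dict[tuple[int, ...], None] = {}
    for es in sorted(totals, key=lambda e: (-totals[e], e)):
        comps.setdefault(_span_composition(es, E), None)
        if len(comps) >= K_max - 1:
            break
    observed = sorted({i for t in X.catalog for i in t.exon_set})
    comps.setdefault(tuple(1 if i + 1 in observed else 0 for i in range(E)), None)
    comps.setdefault(tuple([1] * E), None)
    return [Isoform(c) for c in comps]


def _get_prior(state: VariationalState, X: ReadTermMatrix) -> np.ndarray:
    """Per-isoform emission Dirichlet prior eta_v*(b_kv + eps), cached per catalog."""
    codes = tuple(iso.code for iso in state.catalog)
    if state._prior_key != codes or state._prior is None:
        b = np.array(
            [[compatibility(t, iso) for t in X.catalog] for iso in state.catalog],
            dtype=float,
        )
        state._prior = state.hyp.eta * (b + state.hyp.eps)
        state._prior_key = codes
    return state._prior


def _init_params(
    state: VariationalState, X: ReadTermMatrix, rng
) -> None:
    K = state.K
    prior = _get_prior(state, X)
    share = prior / prior.sum(axis=1, keepdims=True)
    total = X.X.sum()
    jitter = 1.0 + 0.1 * rng.random((K, X.V))
    state.lam = prior + (total / max(K, 1)) * share * jitter
    state.u = np.ones(K)
    state.v = np.full(K, state.hyp.omega)


def _select_rows(state: VariationalState, keep: list[int]) -> None:
    state.catalog = [state.catalog[k] for k in keep]
    state.lam = state.lam[keep]
    state.u = state.u[keep]
    state.v = state.v[keep]


# ---------------------------------------------------------------------------
# Catalog moves
# ---------------------------------------------------------------------------


def merge_step(
    state: VariationalState, X: ReadTermMatrix, precomputed=None
) -> VariationalState:
    """Fuse isoform pairs whenever pooling their mass does not lower the
    plug-in data likelihood.

    For each pair both member compositions are tried as the survivor: the
    pair's proportions are pooled onto it, the per-sample mixture weights
    re-optimised by a few EM steps, and the data likelihood compared with
    the pre-merge value.  Acceptance requires no decrease, so duplicate
    slots (equal likelihood) collapse, preferring fewer isoforms."""
    if state.K < 2:
        return state
    if precomputed is None:
        precomputed = _plugin_mixture(state, X)
    p, beta, _, _, _ = precomputed
    beta = beta.copy()
    polish = state.config.merge_polish_iters
    # BIC-style allowance for the m per-sample mixture weights a merge removes;
    # without it the pooled likelihood can never beat the extra slot's freedom
    # to fit per-sample sampling noise
    n_bar = max(X.X.sum() / X.m, 2.0)
    slack = 0.5 * X.m * np.log(n_bar)
    ll0 = _loglik_from(p, beta, X)
    while state.K > 1:
        # best-first: evaluate every ordered pair and take the candidate with
        # the highest post-merge likelihood, so removing a redundant isoform
        # (often free) is preferred over eroding a supported one
        best = None
        for i in range(state.K):
            for j in range(state.K):
                if i == j:
                    continue
                winner, loser = i, j
                w = winner if winner < loser else winner - 1
                p2 = np.delete(p, loser, axis=1)
                p2[:, w] = p[:, winner] + p[:, loser]
                b2 = np.delete(beta, loser, axis=0)
                p2 = _em_polish(p2, b2, X, polish)
                ll = _loglik_from(p2, b2, X)
                if best is None or ll > best[0]:
                    best = (ll, winner, loser, p2, b2)
        ll_best, winner, loser, p2, b2 = best
        if ll_best < ll0 - slack:
            break
        assert ll_best >= ll0 - slack  # merges never lower the
        # complexity-adjusted likelihood
        state.moves_log.append(
            ("merge", state.catalog[loser].composition,
             state.catalog[winner].composition, ll0, ll_best)
        )
        prior = _get_prior(state, X)
        gain = np.clip(state.lam[loser] - prior[loser], 0, None)
        compat_w = (prior[winner] > state.hyp.eta * state.hyp.eps * 1.5)
        state.lam[winner] += gain * compat_w
        keep = [k for k in range(state.K) if k != loser]
        _select_rows(state, keep)
        p, beta, ll0 = p2, b2, ll_best
    return state


def propose_step(
    state: VariationalState, X: ReadTermMatrix, rng, precomputed=None
) -> tuple[VariationalState, bool]:
    """Propose isoforms from exon unions of poorly mapped read terms.

    A term is poorly mapped when its best responsibility to any existing
    isoform, over all samples carrying it, falls below the configured
    threshold.  Novel distinct compositions enlarge the catalog and trigger
    a full reinitialisation of the variational parameters (catalog kept)."""
    if precomputed is None:
        precomputed = _plugin_mixture(state, X)
    _, _, resp, _, _ = precomputed
    # mapping quality counts only junction-consistent isoforms: a term
    # incompatible with the whole catalog maps nowhere even when K = 1
    prior = _get_prior(state, X)
    compat = (prior > state.hyp.eta * state.hyp.eps * 1.5).astype(float)  # K x V
    best = (resp * compat.T[None, :, :]).max(axis=2)         # m x V
    poor = (X.X.T > 0) & (best < state.config.poor_map_threshold)
    js, vs = np.nonzero(poor)                                # read (sample, term) pairs
    if len(vs) == 0:
        return state, False
    weights = X.X[vs, js].astype(float)
    weights /= weights.sum()
    existing = {iso.composition for iso in state.catalog}
    novel: dict[tuple[int, ...], None] = {}
    E = len(state.catalog[0].composition)
    for _ in range(state.config.max_proposals):
        size = int(rng.integers(1, min(len(vs), 4) + 1))
        chosen = rng.choice(len(vs), size=size, replace=False, p=weights)
        union = {i for c in chosen for i in X.catalog[vs[c]].exon_set}
        comp = tuple(1 if i + 1 in union else 0 for i in range(E))
        if any(comp) and comp not in existing:
            novel.setdefault(comp)
    room = state.hyp.K_max - state.K
    accepted = list(novel)[:room]
    if not accepted:
        return state, False
    state.catalog = state.catalog + [Isoform(c) for c in accepted]
    state.moves_log.append(("propose", accepted))
    _init_params(state, X, rng)  # full reinitialisation, catalog kept
    return state, True


def reduce_step(
    state: VariationalState, X: ReadTermMatrix, precomputed=None
) -> VariationalState:
    """Remove isoforms no read maps to with probability above the threshold;
    the final remaining isoform is never removed.

    Mapping probabilities are taken from a short uniform-weight EM rather
    than the converged weights: the question is whether any read could
    plausibly map to the isoform, not whether the current optimum happens to
    use it (mixture optima can be flat across redundant compositions)."""
    if state.K < 2:
        return state
    beta = _model_beta(state, X)
    p_u = _em_polish(np.full((X.m, state.K), 1.0 / state.K), beta, X, 20)
    resp = p_u[:, None, :] * beta.T[None, :, :]
    resp /= resp.sum(axis=2, keepdims=True)
    observed = X.X.T[:, :, None] > 0                          # m x V x 1
    support = np.where(observed, resp, 0.0).max(axis=(0, 1))  # per k
    keep = [k for k in range(state.K) if support[k] > state.config.reduce_threshold]
    if not keep:
        keep = [int(np.argmax(support))]
    if len(keep) < state.K:
        state.moves_log.append(
            ("reduce", [state.catalog[k].composition
                        for k in range(state.K) if k not in keep])
        )
        _select_rows(state, keep)
    return state


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _fit_single(
    X: ReadTermMatrix, gene: GeneModel, hyp: Hyperparameters, cfg: FitConfig, seed
) -> VariationalState:
    rng = np.random.default_rng(seed)
    state = VariationalState(
        _initial_catalog(X, gene.E, hyp.K_max), np.empty(0), np.empty(0),
        np.empty(0), hyp, cfg,
    )
    _init_params(state, X, rng)
    m = X.m
    prev_ll, stable = -np.inf, 0
    for t in range(1, cfg.max_iter + 1):
        state.iteration = t
        batch = rng.choice(m, size=min(cfg.minibatch, m), replace=False)
        elog_beta = _elog_dirichlet(state.lam)
        elog_sigma = _elog_sticks(state.u, state.v)
        zeta, phi, a, b = _local_step(
            X.X[:, batch], elog_beta, elog_sigma, hyp, cfg.inner_iters
        )
        scale = m / len(batch)
        rho = (t + cfg.delay) ** (-cfg.forgetting)
        weighted = X.X[:, batch].T[:, :, None] * zeta              # B x V x L
        suff = np.einsum("bvl,blk->kv", weighted, phi, optimize=True)
        prior = _get_prior(state, X)
        # b_kv = 0 outside compatible terms: read mass lands only where b_kv = 1,
        # keeping incompatible emissions at the eps floor
        compat = prior > state.hyp.eta * state.hyp.eps * 1.5
        lam_hat = prior + scale * suff * compat
        phi_tot = phi.sum(axis=(0, 1))                             # per k
        u_hat = 1.0 + scale * phi_tot
        tail = np.cumsum(phi_tot[::-1])[::-1] - phi_tot
        v_hat = hyp.omega + scale * tail
        state.lam = (1 - rho) * state.lam + rho * lam_hat
        state.u = (1 - rho) * state.u + rho * u_hat
        state.v = (1 - rho) * state.v + rho * v_hat

        # stochastic likelihood estimate from the minibatch, recorded always
        p_b = _mixture_from_local(phi, a, b)
        mix_b = np.clip(p_b @ _model_beta(state, X), 1e-300, None)
        ll_est = scale * float((X.X[:, batch].T * np.log(mix_b)).sum())
        state.trace.append({"iteration": t, "loglik": ll_est, "K": state.K})

        moved = False
        if t % cfg.move_period == 0:
            k_before = state.K
            pre = _plugin_mixture(state, X)
            state = merge_step(state, X, pre)
            state, proposed = propose_step(state, X, rng)
            state = reduce_step(state, X)
            moved = proposed or state.K != k_before
            state.trace[-1]["K"] = state.K

        if t % cfg.check_every == 0 or moved:
            _, _, _, _, ll = _plugin_mixture(state, X)
            state.trace[-1]["loglik_full"] = ll
            if moved:
                stable = 0
            elif np.isfinite(prev_ll):
                rel = abs(ll - prev_ll) / max(abs(prev_ll), 1.0)
                stable = stable + 1 if rel < cfg.tol else 0
            prev_ll = ll
            if stable >= 2 and t > cfg.move_period:
                state.converged = True
                break
    # final per-sample proportions: mixture-weight EM under the model
    # emissions (the read-allocation E-step), sharper than the truncated
    # slot representation used during the stochastic updates
    state.p, _, state.resp, state.phi, state.loglik = _plugin_mixture(state, X)
    state.score = state.loglik + _catalog_log_prior(state, gene.E)
    return state


def fit(
    X: ReadTermMatrix,
    gene: GeneModel,
    hyp: Hyperparameters | None = None,
    cfg: FitConfig | None = None,
) -> VariationalState:
    """Fit the model by SVI and return the best restart's state.

    Restarts are independently seeded from ``cfg.seed``; the winner maximises
    the plug-in MAP score (data log likelihood plus the uniform base-measure
    catalog prior).  Non-convergence within ``max_iter`` is flagged on the
    returned state, not raised.
    """
    hyp = hyp or Hyperparameters()
    cfg = cfg or FitConfig()
    if X.V < 1 or X.m < 1 or X.X.sum() == 0:
        raise DegenerateDataError("count matrix carries no reads")
    best: VariationalState | None = None
    for r in range(cfg.restarts):
        state = _fit_single(X, gene, hyp, cfg, seed=[cfg.seed, r])
        if best is None or state.score > best.score:
            best = state
    return best
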