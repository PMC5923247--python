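"""Group-specific splicing statistics on transcript-ratio matrices.

Two analyses are provided.  First, a likelihood-ratio test of whether groups
of samples (populations, sexes) draw their per-gene transcript-ratio vectors
from group-specific Dirichlet distributions rather than one shared Dirichlet:
2*(sum_g logL(theta_g) - logL(theta_pooled)) ~ chi2 with (G-1)*T degrees of
freedom for G groups and T transcripts, using maximum-likelihood Dirichlet
fits.  Second, population-specific allele calls (an allele whose count in one
population exceeds a fraction t of its total) with a hypergeometric test for
their over-representation in a selected gene set versus a background set.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, gammaln, polygamma

from .errors import DegenerateDataError

RATIO_FLOOR = 1e-6  # Dirichlet support excludes exact zeros


# ---------------------------------------------------------------------------
# Transcript filters
# ---------------------------------------------------------------------------


def filter_transcripts(
    ratios: pd.DataFrame,
    n_exons: int | None = None,
    min_expressed_frac: float = 0.1,
) -> pd.DataFrame | None:
    """Apply the transcript and gene filters to one gene's ratio matrix.

    ``ratios`` is samples x transcripts.  Transcripts with a constant ratio
    of 0 or 1 across all samples and transcripts expressed (ratio > 0) in
    fewer than ``min_expressed_frac`` of the samples are dropped.  Genes left
    with a single transcript, or with fewer than three exons when ``n_exons``
    is given, are dropped entirely (returns None).
    """
    ratios = pd.DataFrame(ratios)
    n = len(ratios)
    keep = []
    for col in ratios.columns:
        x = ratios[col].to_numpy(dtype=float)
        if np.all(x == 0) or np.all(x == 1):
            continue
        if (x > 0).sum() < min_expressed_frac * n:
            continue
        keep.append(col)
    if len(keep) < 2:
        return None
    if n_exons is not None and n_exons < 3:
        return None
    return ratios[keep]


# ---------------------------------------------------------------------------
# Dirichlet maximum likelihood
# ---------------------------------------------------------------------------


def _clamp_simplex(x: np.ndarray) -> np.ndarray:
    x = np.clip(np.asarray(x, dtype=float), RATIO_FLOOR, None)
    return x / x.sum(axis=-1, keepdims=True)


def dirichlet_loglik(theta: np.ndarray, x: np.ndarray) -> float:
    x = _clamp_simplex(np.atleast_2d(x))
    theta = np.asarray(theta, dtype=float)
    n = x.shape[0]
    return float(
        n * (gammaln(theta.sum()) - gammaln(theta).sum())
        + ((theta - 1) * np.log(x)).sum()
    )


def dirichlet_mle(
    x: np.ndarray, tol: float = 1e-10, max_iter: int = 2000
) -> np.ndarray:
    """Dirichlet MLE by Minka's fixed-point iteration with Newton polishing.

    Rows of ``x`` are simplex observations; zero components are clamped to a
    small floor before taking logs.  Convergence is declared at gradient norm
    below 1e-8; identical rows make the MLE diverge and raise
    :class:`DegenerateDataError`.
    """
    x = _clamp_simplex(np.atleast_2d(np.asarray(x, dtype=float)))
    n, d = x.shape
    if n < 2:
        raise ValueError("need at least 2 samples for a Dirichlet MLE")
    if d < 2:
        raise ValueError("need dimension >= 2")
    if np.allclose(x, x[0], atol=1e-12):
        raise DegenerateDataError("all observations identical: MLE diverges")
    logx_bar = np.log(x).mean(axis=0)
    mean = x.mean(axis=0)
    var = x.var(axis=0).mean()
    # method-of-moments start for the concentration
    s0 = max((mean[0] * (1 - mean[0])) / max(var, 1e-12) - 1.0, 1e-3)
    theta = np.clip(mean * s0, 1e-3, None)
    for _ in range(max_iter):
        theta_new = _inv_digamma(digamma(theta.sum()) + logx_bar)
        theta_new = np.clip(theta_new, 1e-8, 1e8)
        if np.max(np.abs(theta_new - theta)) < tol:
            theta = theta_new
            break
        theta = theta_new
    # Newton polish with the closed-form Hessian inverse drives the gradient
    # norm to the stated tolerance (the fixed point converges only linearly)
    for _ in range(100):
        grad = n * (digamma(theta.sum()) - digamma(theta) + logx_bar)
        if np.linalg.norm(grad) < 1e-8:
            break
        q = -n * polygamma(1, theta)
        z = n * polygamma(1, theta.sum())
        b = (grad / q).sum() / (1.0 / z + (1.0 / q).sum())
        step = (grad - b) / q
        scale = 1.0
        while np.any(theta - scale * step <= 0) and scale > 1e-8:
            scale /= 2
        theta = theta - scale * step
    grad = n * (digamma(theta.sum()) - digamma(theta) + logx_bar)
    if np.linalg.norm(grad) >= 1e-8:
        warnings.warn("Dirichlet MLE did not reach gradient tolerance", RuntimeWarning)
    return theta


def _inv_digamma(y: np.ndarray, iters: int = 5) -> np.ndarray:
    """Invert digamma by Newton from Minka's initialisation."""
    y = np.asarray(y, dtype=float)
    x = np.where(y >= -2.22, np.exp(y) + 0.5, -1.0 / (y - digamma(1.0)))
    for _ in range(iters):
        x = x - (digamma(x) - y) / polygamma(1, x)
        x = np.clip(x, 1e-12, None)
    return x


def dirichlet_moment_start(x: np.ndarray) -> np.ndarray:
    """Method-of-moments Dirichlet estimate (used as a sanity baseline)."""
    x = _clamp_simplex(np.atleast_2d(np.asarray(x, dtype=float)))
    mean = x.mean(axis=0)
    var = x.var(axis=0).mean()
    s0 = max((mean[0] * (1 - mean[0])) / max(var, 1e-12) - 1.0, 1e-3)
    return np.clip(mean * s0, 1e-3, None)


# ---------------------------------------------------------------------------
# Likelihood-ratio test for group-specific transcript ratios
# ---------------------------------------------------------------------------


def lr_test(
    ratios: np.ndarray, groups: Sequence
) -> tuple[float, int, float]:
    """LR test of group-specific vs shared Dirichlet transcript ratios.

    Returns (statistic, degrees of freedom, p-value) with
    statistic = 2*(sum_g logL(theta_g | x_g) - logL(theta_pooled | x)),
    df = (G-1)*T, p from the chi-square upper tail.  Groups with fewer than
    two samples are excluded with a warning; fewer than two usable groups is
    an error.  Multiple-testing correction across genes is the caller's job.
    """
    ratios = np.atleast_2d(np.asarray(ratios, dtype=float))
    groups = np.asarray(groups)
    if len(groups) != ratios.shape[0]:
        raise ValueError("one group label per sample row required")
    usable = []
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        if len(idx) < 2:
            warnings.warn(f"group {g!r} has < 2 samples; excluded", UserWarning)
            continue
        usable.append(idx)
    if len(usable) < 2:
        raise ValueError("need at least two groups with >= 2 samples")
    rows = np.concatenate(usable)
    pooled = dirichlet_mle(ratios[rows])
    ll_pooled = dirichlet_loglik(pooled, ratios[rows])
    ll_groups = 0.0
    for idx in usable:
        theta_g = dirichlet_mle(ratios[idx])
        ll_groups += dirichlet_loglik(theta_g, ratios[idx])
    statistic = max(2.0 * (ll_groups - ll_pooled), 0.0)
    df = (len(usable) - 1) * ratios.shape[1]
    pval = float(stats.chi2.sf(statistic, df))
    return statistic, df, pval


# ---------------------------------------------------------------------------
# Population-specific alleles and enrichment
# ---------------------------------------------------------------------------


def population_specific(counts: Mapping[str, Mapping[str, float]], t: float) -> bool:
    """A variant is population-specific if some allele's count in some
    population exceeds fraction ``t`` of that allele's total across
    populations (strict inequality).  ``counts`` maps allele -> population ->
    count; alleles with zero total count are skipped.
    """
    if not 0 <= t < 1:
        raise ValueError("t must lie in [0, 1)")
    for allele, per_pop in counts.items():
        total = sum(per_pop.values())
        if total == 0:
            continue
        if any(c / total > t for c in per_pop.values()):
            return True
    return False


def variant_table_specific(
    variants: pd.DataFrame, t: float, maf_min: float = 0.0
) -> pd.Series:
    """Per-variant population-specific calls from a tidy variant table.

    ``variants`` columns: variant, allele, population, count, MAF.  A variant
    with MAF below ``maf_min`` is called False.
    """
    calls = {}
    for vid, sub in variants.groupby("variant"):
        if float(sub["MAF"].iloc[0]) < maf_min:
            calls[vid] = False
            continue
        counts: dict[str, dict[str, float]] = {}
        for allele, pop, cnt in zip(sub["allele"], sub["population"], sub["count"]):
            counts.setdefault(allele, {})[pop] = float(cnt)
        calls[vid] = population_specific(counts, t)
    return pd.Series(calls, name="specific")


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeom(N population, K successes, n draws)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrichment_test(
    selected_genes: Sequence[str],
    background_genes: Sequence[str],
    variants: pd.DataFrame,
    maf_min: float,
    t: float,
) -> float:
    """Hypergeometric over-representation of population-specific alleles.

    Variants (pre-pruned for LD by the caller) are assigned to genes via the
    table's ``gene`` column.  The urn is all variants in selected+background
    genes; successes are the population-specific calls at MAF >= maf_min; the
    draw is the selected set.  Returns the upper-tail probability of the
    selected count.
    """
    selected = set(selected_genes)
    background = set(background_genes)
    if selected & background:
        raise ValueError("selected and background gene sets must be disjoint")
    if not background:
        raise ValueError("background gene set is empty")
    table = variants[variants["gene"].isin(selected | background)]
    calls = variant_table_specific(table, t, maf_min)
    gene_of = table.groupby("variant")["gene"].first()
    in_selected = gene_of.loc[calls.index].isin(selected)
    N = len(calls)
    K = int(calls.sum())
    n = int(in_selected.sum())
    k = int(calls[in_selected].sum())
    return hypergeom_upper_tail(k, N, K, n)
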