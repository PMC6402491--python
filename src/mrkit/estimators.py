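"""Causal-effect estimators for summary-data Mendelian randomization.

Given harmonized per-SNP effects (gamma_i on the exposure, beta_i on the
outcome, both log odds ratios), each SNP supplies a Wald ratio estimate
alpha_i = beta_i / gamma_i of the causal effect alpha with first-order
variance v_i = (se(beta_i) / gamma_i)^2. The inverse-variance weighted
(IVW) estimator is the w_i = 1/v_i weighted mean of the ratios; its
fixed-effect standard error is (sum w_i)^{-1/2}, and the multiplicative
random-effects flavour inflates that SE by sqrt(Q / (n-1)) when
Cochran's Q exceeds its degrees of freedom. The weighted median is the
0.5 quantile of the weight-ordered ratios and stays consistent when up
to half of the instrument weight is invalid; its SE comes from a
parametric bootstrap.

All estimates are on the log-odds scale; ``to_odds_ratio`` maps a
result onto the odds-ratio scale for reporting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .gwas_io import HarmonizedSet

logger = logging.getLogger(__name__)

Z_95 = 1.96  # normal 95% CI multiplier


@dataclass
class MRResult:
    """A causal-effect estimate on the log-odds scale."""

    method: str
    alpha: float
    se_alpha: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    or_scale: tuple[float, float, float] | None = None  # (OR, low, high)

    def __post_init__(self) -> None:
        if self.se_alpha <= 0:
            raise ValueError("se_alpha must be positive")
        if not (self.ci_low < self.alpha < self.ci_high):
            raise ValueError("CI must bracket the point estimate")


@dataclass(frozen=True)
class HeterogeneityStats:
    """Cochran's Q heterogeneity test across per-SNP Wald ratios."""

    q: float
    df: int
    p_het: float
    i2: float  # percentage in [0, 100)


def wald_ratio(gamma: float, se_gamma: float, beta: float, se_beta: float) -> tuple[float, float]:
    """Single-SNP causal estimate and its first-order variance.

    Returns (alpha_i, v_i) with alpha_i = beta/gamma and
    v_i = (se_beta/gamma)^2; the exposure-side uncertainty ``se_gamma``
    is accepted but does not enter the first-order variance.
    """
    if gamma == 0:
        raise ValueError("undefined ratio: gamma is zero")
    if se_beta <= 0:
        raise ValueError("se_beta must be positive")
    return beta / gamma, (se_beta / gamma) ** 2


def _ratios_and_weights(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    if np.any(hset.gamma == 0):
        raise ValueError("undefined ratio: gamma is zero")
    alpha_i = hset.beta / hset.gamma
    w = (hset.gamma / hset.se_beta) ** 2  # 1 / v_i
    return alpha_i, w


def _finalize(method: str, alpha: float, se: float, n: int) -> MRResult:
    z = alpha / se
    return MRResult(
        method=method,
        alpha=alpha,
        se_alpha=se,
        ci_low=alpha - Z_95 * se,
        ci_high=alpha + Z_95 * se,
        pvalue=float(2.0 * stats.norm.sf(abs(z))),
        n_snps=n,
    )


def ivw(hset: HarmonizedSet, mode: str = "multiplicative_random") -> MRResult:
    """Inverse-variance weighted estimate of the causal effect.

    ``mode="fixed"`` uses SE = (sum w_i)^{-1/2}. The default
    ``"multiplicative_random"`` inflates that SE by
    max(1, sqrt(Q/(n-1))), absorbing between-SNP heterogeneity without
    re-weighting — the usual random-effects convention for summary-data
    MR. A single instrument forces fixed mode (Q is undefined).
    """
    if mode not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW mode {mode!r}")
    n = hset.n_snps
    if n == 0:
        raise ValueError("no instruments")
    alpha_i, w = _ratios_and_weights(hset)
    alpha = float(np.sum(alpha_i * w) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    label = "ivw_fixed"
    if mode == "multiplicative_random":
        if n == 1:
            logger.info("single instrument: random-effects IVW falls back to fixed")
        else:
            q = float(np.sum(w * (alpha_i - alpha) ** 2))
            se *= max(1.0, math.sqrt(q / (n - 1)))
        label = "ivw_random"
    return _finalize(label, alpha, se, n)


def cochran_q(hset: HarmonizedSet, alpha_hat: float | None = None) -> HeterogeneityStats:
    """Cochran's Q = sum w_i (alpha_i - alpha_hat)^2 with df = n-1,
    plus the I^2 fraction of variation attributable to heterogeneity.

    ``alpha_hat`` defaults to the fixed-effect IVW estimate.
    """
    n = hset.n_snps
    if n < 2:
        raise ValueError("Cochran's Q needs at least 2 instruments")
    alpha_i, w = _ratios_and_weights(hset)
    if alpha_hat is None:
        alpha_hat = float(np.sum(alpha_i * w) / np.sum(w))
    q = float(np.sum(w * (alpha_i - alpha_hat) ** 2))
    df = n - 1
    p_het = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return HeterogeneityStats(q=q, df=df, p_het=p_het, i2=i2)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted 0.5 quantile with linear interpolation between the
    order statistics at standardized cumulative weights
    s_j = (cumsum(w)_j - w_j/2) / sum(w)."""
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, v))


def weighted_median_point(hset: HarmonizedSet) -> float:
    """Weighted-median point estimate only (no bootstrap SE)."""
    if hset.n_snps < 3:
        raise ValueError("weighted median needs at least 3 instruments")
    alpha_i, w = _ratios_and_weights(hset)
    return _weighted_median(alpha_i, w)


def weighted_median(
    hset: HarmonizedSet,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MRResult:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    The point estimate is the inverse-variance weighted median of the
    Wald ratios, consistent as long as valid instruments carry at least
    50% of the total weight. The SE is the standard deviation of the
    estimate across ``n_boot`` replicates in which gamma_i and beta_i
    are redrawn from normal(observed, SE).
    """
    n = hset.n_snps
    if n < 3:
        raise ValueError("weighted median needs at least 3 instruments")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed")
    alpha_i, w = _ratios_and_weights(hset)
    point = _weighted_median(alpha_i, w)

    rng = np.random.default_rng(seed)
    g_star = rng.normal(hset.gamma, hset.se_gamma, size=(n_boot, n))
    b_star = rng.normal(hset.beta, hset.se_beta, size=(n_boot, n))
    # guard exact zeros in resampled gamma (measure-zero but finite-precision)
    g_star[g_star == 0] = np.finfo(float).tiny
    ratios = b_star / g_star
    weights = (g_star / hset.se_beta) ** 2

    order = np.argsort(ratios, axis=1, kind="stable")
    r_sorted = np.take_along_axis(ratios, order, axis=1)
    w_sorted = np.take_along_axis(weights, order, axis=1)
    cum = np.cumsum(w_sorted, axis=1)
    s = (cum - 0.5 * w_sorted) / cum[:, -1:]
    boots = np.empty(n_boot)
    for k in range(n_boot):
        boots[k] = np.interp(0.5, s[k], r_sorted[k])
    se = float(np.std(boots, ddof=1))
    return _finalize("weighted_median", point, se, n)


def to_odds_ratio(result: MRResult) -> MRResult:
    """Populate the odds-ratio view: exp of the estimate and CI bounds."""
    return replace(
        result,
        or_scale=(math.exp(result.alpha), math.exp(result.ci_low), math.exp(result.ci_high)),
    )


def format_or(result: MRResult) -> str:
    """Render ``OR (low-high)`` rounded to 2 decimals, as in published
    MR tables."""
    res = result if result.or_scale is not None else to_odds_ratio(result)
    o, lo, hi = res.or_scale
    return f"{o:.2f} ({lo:.2f}–{hi:.2f})"


def format_p(p: float) -> str:
    """p-values to 2 significant figures, scientific below 1e-3."""
    if p == 0:
        return "0"
    if p < 1e-3:
        return f"{p:.1e}"
    return f"{float(f'{p:.2g}'):g}"
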