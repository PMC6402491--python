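"""MR-PRESSO: residual-sum-of-squares pleiotropy diagnostics.

Horizontal pleiotropy — a variant influencing the outcome through a
pathway other than the exposure — violates the exclusion restriction
and distorts MR estimates. The PRESSO framework detects it by comparing
each SNP's outcome effect with the value predicted from the causal fit
of all *other* SNPs:

- **global test**: the observed weighted residual sum of squares
  RSS = sum_i (beta_i - alphahat_(-i) * gamma_i)^2 / se(beta_i)^2,
  where alphahat_(-i) is the leave-one-out fixed-effect IVW estimate,
  is referred to a parametric null distribution built by redrawing
  gamma*_i ~ N(gamma_i, se_gamma_i) and
  beta*_i ~ N(alphahat_(-i) gamma_i, se_beta_i) and recomputing RSS;
- **outlier test**: the same comparison per SNP, Bonferroni-corrected;
- **distortion test**: whether removing the flagged SNPs shifts the IVW
  estimate more than removing equally many random SNPs would.

Empirical p-values carry the add-one correction, so they are never 0
and never below 1/(n_sim + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .estimators import ivw
from .gwas_io import HarmonizedSet

logger = logging.getLogger(__name__)


@dataclass
class PressoReport:
    """Outcome of the global, outlier and (optional) distortion tests."""

    global_rss_obs: float
    global_p: float
    outlier_ids: list[str]
    per_snp_p: dict[str, float]
    distortion_p: float | None
    n_sim: int
    seed: int


def _loo_residuals(gamma: np.ndarray, beta: np.ndarray, se_beta: np.ndarray):
    """Per-SNP squared residual against the leave-one-out IVW fit,
    standardized by the outcome variance. Vectorized over leading axes.

    Returns (residuals, loo_slopes), each with gamma's shape.
    """
    t_num = beta * gamma / se_beta**2
    t_den = gamma**2 / se_beta**2
    s_num = t_num.sum(axis=-1, keepdims=True)
    s_den = t_den.sum(axis=-1, keepdims=True)
    den = s_den - t_den
    if np.any(den <= 0):
        raise ValueError("degenerate leave-one-out fit (need >= 2 informative SNPs)")
    slope_loo = (s_num - t_num) / den
    resid = (beta - slope_loo * gamma) ** 2 / se_beta**2
    return resid, slope_loo


def _simulate_rss(
    hset: HarmonizedSet, n_sim: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed per-SNP residuals plus their parametric null.

    Returns (obs_resid [n], sim_resid [n_sim, n], sim_rss [n_sim]).
    """
    if hset.n_snps < 4:
        raise ValueError("MR-PRESSO needs at least 4 instruments")
    if np.any(hset.se_beta <= 0) or np.any(hset.se_gamma <= 0):
        raise ValueError("degenerate standard error")
    obs_resid, loo = _loo_residuals(hset.gamma, hset.beta, hset.se_beta)
    g_star = rng.normal(hset.gamma, hset.se_gamma, size=(n_sim, hset.n_snps))
    b_star = rng.normal(loo * hset.gamma, hset.se_beta, size=(n_sim, hset.n_snps))
    sim_resid, _ = _loo_residuals(g_star, b_star, hset.se_beta)
    return obs_resid, sim_resid, sim_resid.sum(axis=1)


def _empirical_p(exceed_count: int | np.ndarray, n_sim: int):
    return (1 + exceed_count) / (n_sim + 1)


def global_test(hset: HarmonizedSet, n_sim: int = 5000, seed: int | None = None) -> tuple[float, float]:
    """Global pleiotropy test: observed RSS vs its parametric null.

    Returns (rss_obs, global_p) with the empirical add-one p-value.
    """
    if n_sim < 1000:
        raise ValueError("n_sim must be at least 1000")
    if seed is None:
        raise ValueError("global_test requires an explicit seed")
    rng = np.random.default_rng(seed)
    obs_resid, _, sim_rss = _simulate_rss(hset, n_sim, rng)
    rss_obs = float(obs_resid.sum())
    p = float(_empirical_p(int(np.sum(sim_rss >= rss_obs)), n_sim))
    return rss_obs, p


def outlier_test(
    hset: HarmonizedSet,
    n_sim: int = 5000,
    seed: int | None = None,
    alpha_level: float = 0.05,
) -> tuple[list[str], dict[str, float]]:
    """Per-SNP pleiotropy test with Bonferroni correction.

    A SNP is flagged when its empirical residual p-value falls below
    ``alpha_level / n_snps``.
    """
    if n_sim < 1000:
        raise ValueError("n_sim must be at least 1000")
    if seed is None:
        raise ValueError("outlier_test requires an explicit seed")
    rng = np.random.default_rng(seed)
    obs_resid, sim_resid, _ = _simulate_rss(hset, n_sim, rng)
    exceed = (sim_resid >= obs_resid[None, :]).sum(axis=0)
    p_per_snp = _empirical_p(exceed, n_sim)
    cutoff = alpha_level / hset.n_snps
    per_snp = {sid: float(p) for sid, p in zip(hset.snp_ids, p_per_snp)}
    flagged = [sid for sid, p in per_snp.items() if p < cutoff]
    for sid in flagged:
        logger.info("outlier_test: flagged %s (p=%.2e < %.2e)", sid, per_snp[sid], cutoff)
    return flagged, per_snp


def distortion_test(
    hset: HarmonizedSet,
    outlier_ids: list[str],
    n_sim: int = 5000,
    seed: int | None = None,
) -> float:
    """Does removing the flagged outliers shift the causal estimate more
    than removing an equally sized random subset would?

    Returns the two-sided empirical p-value of the observed shift
    against the random-subset null.
    """
    if not outlier_ids:
        raise ValueError("nothing to test: outlier_ids is empty")
    if seed is None:
        raise ValueError("distortion_test requires an explicit seed")
    rng = np.random.default_rng(seed)
    n = hset.n_snps
    k = len(outlier_ids)
    outlier_set = set(outlier_ids)
    missing = outlier_set - set(hset.snp_ids)
    if missing:
        raise ValueError(f"outlier id not in set: {sorted(missing)[0]}")
    if n - k < 2:
        raise ValueError("too few instruments would remain after removal")
    alpha_all = ivw(hset, mode="fixed").alpha
    keep = [sid not in outlier_set for sid in hset.snp_ids]
    alpha_clean = ivw(hset.subset(keep), mode="fixed").alpha
    obs_diff = alpha_clean - alpha_all

    null_diffs = np.empty(n_sim)
    idx = np.arange(n)
    for j in range(n_sim):
        drop = rng.choice(idx, size=k, replace=False)
        mask = np.ones(n, dtype=bool)
        mask[drop] = False
        null_diffs[j] = ivw(hset.subset(mask), mode="fixed").alpha - alpha_all
    p = float(_empirical_p(int(np.sum(np.abs(null_diffs) >= abs(obs_diff))), n_sim))
    return p


def run_presso(
    hset: HarmonizedSet,
    n_sim: int = 5000,
    seed: int | None = None,
    alpha_level: float = 0.05,
    distortion: bool = True,
    distortion_n_sim: int = 1000,
) -> PressoReport:
    """Run the global, outlier and (when outliers are found) distortion
    tests with a single seed; same seed and input give a bit-identical
    report."""
    rss_obs, global_p = global_test(hset, n_sim=n_sim, seed=seed)
    outliers, per_snp = outlier_test(hset, n_sim=n_sim, seed=seed, alpha_level=alpha_level)
    distortion_p = None
    if distortion and outliers:
        distortion_p = distortion_test(
            hset, outliers, n_sim=distortion_n_sim, seed=seed + 1
        )
    return PressoReport(
        global_rss_obs=rss_obs,
        global_p=global_p,
        outlier_ids=outliers,
        per_snp_p=per_snp,
        distortion_p=distortion_p,
        n_sim=n_sim,
        seed=seed,
    )


def write_exclusions(path, outlier_ids: list[str]) -> None:
    """Plain-text exclusion list (one snp_id per line) for the pipeline."""
    with open(path, "w") as fh:
        for sid in outlier_ids:
            fh.write(sid + "\n")
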