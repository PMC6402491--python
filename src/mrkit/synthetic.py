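"""Synthetic two-sample GWAS summary statistics with known truth.

The generator emulates the statistical regime of a well-powered
two-sample MR study of two binary traits: per-SNP instrument effects
gamma_i (log odds ratios) with exposure-side standard errors, and
outcome effects

    beta_i = alpha * gamma_i + pleiotropy_i + noise(se_beta_i),

where alpha is the true causal effect. Pleiotropy can be absent,
balanced (zero-mean) or directional (non-zero mean), and a configurable
contamination fraction of SNPs receive a fixed pleiotropic shift of
``outlier_shift`` outcome standard errors — the planted outliers the
PRESSO tests should find. Summary statistics are produced directly on
the log-odds scale; there is no individual-level or case-control
sampling layer.

Defaults mirror a schizophrenia-to-breast-cancer-sized analysis:
170 instruments, true alpha 0.04, instrument effects around 0.10 with
exposure SE 0.010 and outcome SE 0.0095 (per-SNP Wald ratio SE near
0.1), and balanced pleiotropy sized to give mid-range heterogeneity
(I-squared around 45%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import SummaryRecord

# non-palindromic allele pairs only, so default datasets survive
# harmonization regardless of palindrome policy
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"))


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generative model. ``se_gamma``/``se_beta`` accept a
    scalar or a (low, high) range sampled uniformly per SNP."""

    n_snps: int = 170
    true_alpha: float = 0.04
    gamma_mean: float = 0.10
    gamma_sd: float = 0.025
    se_gamma: float | tuple[float, float] = 0.010
    se_beta: float | tuple[float, float] = 0.0095
    pleiotropy_mode: str = "balanced"  # none | balanced | directional
    pleiotropy_sd: float = 0.009
    pleiotropy_mean: float = 0.009  # used by directional mode only
    outlier_fraction: float = 0.0
    outlier_shift: float = 10.0  # in units of se_beta
    maf_range: tuple[float, float] = (0.05, 0.5)
    info_range: tuple[float, float] = (0.6, 1.0)
    add_noise: bool = True  # False: observed effects equal their means
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("invalid config: n_snps must be >= 1")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"invalid config: unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if not (0.0 <= self.outlier_fraction <= 0.5):
            raise ValueError("invalid config: outlier_fraction must be in [0, 0.5]")
        for name in ("gamma_sd", "pleiotropy_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"invalid config: {name} must be >= 0")
        for name in ("se_gamma", "se_beta"):
            v = getattr(self, name)
            lo, hi = (v, v) if np.isscalar(v) else v
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid config: {name} must be positive")
        if not (0.0 <= self.maf_range[0] < self.maf_range[1] <= 0.5 + 1e-12):
            raise ValueError("invalid config: maf_range must be within [0, 0.5]")
        if not (0.0 <= self.info_range[0] <= self.info_range[1] <= 1.0):
            raise ValueError("invalid config: info_range must be within [0, 1]")


@dataclass
class SimulatedDataset:
    """Generated exposure/outcome records plus the generating truth."""

    exposure: list[SummaryRecord]
    outcome: list[SummaryRecord]
    truth: pd.DataFrame  # snp_id, true_gamma, pleiotropy, is_outlier
    true_alpha: float


def _per_snp(rng: np.random.Generator, value, n: int) -> np.ndarray:
    if np.isscalar(value):
        return np.full(n, float(value))
    lo, hi = value
    return rng.uniform(lo, hi, size=n)


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    # keep p inside (0, 1] so records validate
    return np.clip(p, np.finfo(float).tiny, 1.0)


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Draw one dataset from the generative model.

    True instrument effects are normal(gamma_mean, gamma_sd) with the
    sign fixed positive; observed exposure effects add
    normal(0, se_gamma) noise; outcome effects are
    true_alpha * gamma + pleiotropy + normal(0, se_beta). Identical
    config (including seed) gives a bit-identical dataset.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_snps
    true_gamma = np.abs(rng.normal(config.gamma_mean, config.gamma_sd, size=n))
    true_gamma = np.maximum(true_gamma, 1e-6)  # guard exact zeros
    se_g = _per_snp(rng, config.se_gamma, n)
    se_b = _per_snp(rng, config.se_beta, n)

    if config.pleiotropy_mode == "none":
        pleio = np.zeros(n)
    elif config.pleiotropy_mode == "balanced":
        pleio = rng.normal(0.0, config.pleiotropy_sd, size=n)
    else:  # directional
        pleio = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=n)

    n_out = int(round(config.outlier_fraction * n))
    is_outlier = np.zeros(n, dtype=bool)
    if n_out:
        picked = rng.choice(n, size=n_out, replace=False)
        is_outlier[picked] = True
        pleio[picked] = config.outlier_shift * se_b[picked]

    noise = float(config.add_noise)
    obs_gamma = true_gamma + noise * rng.normal(0.0, 1.0, size=n) * se_g
    obs_beta = config.true_alpha * true_gamma + pleio + noise * rng.normal(0.0, 1.0, size=n) * se_b

    maf = rng.uniform(*config.maf_range, size=n)
    info = rng.uniform(*config.info_range, size=n)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)
    p_exp = _two_sided_p(obs_gamma, se_g)
    p_out = _two_sided_p(obs_beta, se_b)

    ids = [f"rs{1000 + i}" for i in range(n)]
    exposure, outcome = [], []
    for i, sid in enumerate(ids):
        ea, oa = _ALLELE_PAIRS[pair_idx[i]]
        exposure.append(
            SummaryRecord(sid, ea, oa, eaf=float(maf[i]), beta=float(obs_gamma[i]),
                          se=float(se_g[i]), pvalue=float(p_exp[i]), info=None)
        )
        outcome.append(
            SummaryRecord(sid, ea, oa, eaf=float(maf[i]), beta=float(obs_beta[i]),
                          se=float(se_b[i]), pvalue=float(p_out[i]), info=float(info[i]))
        )
    truth = pd.DataFrame(
        {
            "snp_id": ids,
            "true_gamma": true_gamma,
            "pleiotropy": pleio,
            "is_outlier": is_outlier,
        }
    )
    return SimulatedDataset(exposure=exposure, outcome=outcome, truth=truth,
                            true_alpha=config.true_alpha)


def simulate_ld_block(
    n_individuals: int,
    n_snps: int,
    correlation: float,
    seed: int,
) -> np.ndarray:
    """Dosage matrix (individuals x SNPs) whose adjacent columns have
    squared correlation near ``correlation``.

    Two haplotypes per individual are generated as Markov chains of
    0/1 alleles at frequency 0.5 in which each allele copies its left
    neighbour with probability (1 + r)/2, r = sqrt(correlation); the
    adjacent allele (and hence dosage) correlation is then exactly r in
    expectation, so adjacent-pair dosage r² targets ``correlation``.
    """
    if not (0.0 <= correlation < 1.0):
        raise ValueError("correlation must be in [0, 1)")
    if n_individuals < 2 or n_snps < 1:
        raise ValueError("need >= 2 individuals and >= 1 SNP")
    rng = np.random.default_rng(seed)
    r = float(np.sqrt(correlation))
    p_copy = (1.0 + r) / 2.0
    dosage = np.zeros((n_individuals, n_snps))
    for _hap in range(2):
        h = np.empty((n_individuals, n_snps), dtype=np.int8)
        h[:, 0] = rng.random(n_individuals) < 0.5
        if n_snps > 1:
            copy = rng.random((n_individuals, n_snps - 1)) < p_copy
            for j in range(1, n_snps):
                h[:, j] = np.where(copy[:, j - 1], h[:, j - 1], 1 - h[:, j - 1])
        dosage += h
    # guard the (astronomically rare at realistic n) all-constant column
    for j in range(n_snps):
        if dosage[:, j].min() == dosage[:, j].max():
            dosage[0, j] = 0.0 if dosage[0, j] > 0 else 1.0
    return dosage


def write_dataset(dataset: SimulatedDataset, exposure_path, outcome_path, truth_path=None) -> None:
    """Write the dataset in the TSV dialect ``gwas_io`` reads; the truth
    table goes alongside when a path is given."""
    from .gwas_io import write_summary_stats

    write_summary_stats(exposure_path, dataset.exposure)
    write_summary_stats(outcome_path, dataset.outcome)
    if truth_path is not None:
        dataset.truth.to_csv(truth_path, sep="\t", index=False)
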