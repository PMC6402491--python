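"""Instrument selection: significance, LD independence, imputation quality.

A valid Mendelian randomization instrument must be robustly associated
with the exposure (genome-wide significance), statistically independent
of the other instruments (pairwise LD r² below a threshold), and well
measured in the outcome sample (imputation info score). Each filter
here is idempotent and logs what it removes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gwas_io import HarmonizedSet, SummaryRecord

logger = logging.getLogger(__name__)


@dataclass
class LDMatrix:
    """Pairwise squared allele-dosage correlations for a set of SNPs."""

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.snp_ids)
        if self.r2.shape != (n, n):
            raise ValueError("r2 must be square with one row per SNP")
        if not np.allclose(self.r2, self.r2.T, atol=1e-10):
            raise ValueError("r2 must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-10):
            raise ValueError("r2 diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 values must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def lookup(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(snp_ids=[str(s) for s in df.index], r2=df.to_numpy(float))


def filter_by_pvalue(records: Sequence[SummaryRecord], threshold: float) -> list[SummaryRecord]:
    """Keep records with p strictly below ``threshold`` (order preserved)."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    return [r for r in records if r.pvalue < threshold]


def compute_r2(genotypes: np.ndarray, snp_ids: Sequence[str] | None = None) -> LDMatrix:
    """Pairwise squared Pearson correlation of dosage columns.

    ``genotypes`` is individuals x SNPs with allele dosages in [0, 2].
    A zero-variance SNP makes the correlation undefined and is an error.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2 or g.shape[0] < 2:
        raise ValueError("genotypes must be a 2-D matrix with >= 2 individuals")
    n_snps = g.shape[1]
    ids = list(snp_ids) if snp_ids is not None else [f"snp{i}" for i in range(n_snps)]
    if len(ids) != n_snps:
        raise ValueError("snp_ids length must match the number of genotype columns")
    variances = g.var(axis=0)
    dead = np.flatnonzero(variances == 0)
    if dead.size:
        raise ValueError(f"zero-variance SNP: {ids[dead[0]]}")
    corr = np.corrcoef(g, rowvar=False)
    r2 = np.clip(corr**2, 0.0, 1.0)
    np.fill_diagonal(r2, 1.0)
    return LDMatrix(snp_ids=ids, r2=r2)


def ld_prune(
    records: Sequence[SummaryRecord],
    ld: LDMatrix,
    r2_threshold: float = 0.1,
) -> list[SummaryRecord]:
    """Greedy LD pruning: keep the most significant SNP, drop everything
    correlated with it above ``r2_threshold``, repeat.

    Ties on p-value are broken by lexicographic snp_id so the result is
    deterministic and independent of input order. The returned set
    contains no pair with r² > ``r2_threshold``.
    """
    missing = [r.snp_id for r in records if r.snp_id not in ld._index]
    if missing:
        raise ValueError(f"record missing from LD matrix: {missing[0]}")
    remaining = sorted(records, key=lambda r: (r.pvalue, r.snp_id))
    kept: list[SummaryRecord] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        pruned = [r for r in remaining if ld.lookup(best.snp_id, r.snp_id) > r2_threshold]
        for r in pruned:
            logger.info("ld_prune: dropped %s (r2=%.3f with index SNP %s)",
                        r.snp_id, ld.lookup(best.snp_id, r.snp_id), best.snp_id)
        remaining = [r for r in remaining if ld.lookup(best.snp_id, r.snp_id) <= r2_threshold]
    order = {r.snp_id: i for i, r in enumerate(records)}
    kept.sort(key=lambda r: order[r.snp_id])
    # postcondition: no retained pair above threshold
    for i, a in enumerate(kept):
        for b in kept[i + 1:]:
            assert ld.lookup(a.snp_id, b.snp_id) <= r2_threshold
    return kept


def filter_by_info(
    hset: HarmonizedSet,
    min_info: float,
    info_source: Mapping[str, float | None],
    boundary_inclusive: bool = True,
    missing_policy: str = "retain",
) -> HarmonizedSet:
    """Drop SNPs whose imputation info score falls below ``min_info``.

    With ``boundary_inclusive`` (default) a score exactly equal to
    ``min_info`` is retained, i.e. only scores strictly below the
    threshold are removed. SNPs with no info score are retained and
    logged by default (``missing_policy="retain"``) or dropped
    (``"drop"``).
    """
    if not (0.0 <= min_info <= 1.0):
        raise ValueError(f"min_info must be in [0, 1], got {min_info}")
    if missing_policy not in ("retain", "drop"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    keep = []
    reasons: dict[str, str] = {}
    for i, sid in enumerate(hset.snp_ids):
        info = info_source.get(sid)
        if info is None:
            if missing_policy == "retain":
                logger.info("filter_by_info: %s has no info score, retained", sid)
                keep.append(i)
            else:
                reasons[sid] = "info-missing"
            continue
        ok = info >= min_info if boundary_inclusive else info > min_info
        if ok:
            keep.append(i)
        else:
            reasons[sid] = "low-info"
    out = hset.subset(keep)
    out.drops.update(reasons)
    return out


def read_genotype_matrix(path) -> tuple[np.ndarray, list[str]]:
    """Read a tab-delimited dosage matrix (individuals as rows, SNPs as
    header columns)."""
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(float), [str(c) for c in df.columns]
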