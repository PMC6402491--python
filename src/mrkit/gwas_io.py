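"""Reading, writing and harmonizing GWAS summary statistics.

Two-sample Mendelian randomization combines per-variant association
estimates from an exposure GWAS and an outcome GWAS. Before any
estimation the two tables must be *harmonized*: expressed per copy of
the same effect allele, on the same strand, with the exposure effect
oriented so that the effect allele increases the exposure. This module
owns the record types and that harmonization step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column names of the summary-statistics dialect
CANONICAL_COLUMNS = (
    "snp_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "info",
)


class FormatError(ValueError):
    """A summary-statistics file violates the expected layout."""


@dataclass(frozen=True)
class SummaryRecord:
    """One SNP's association summary in one GWAS.

    ``beta`` is the log odds ratio per copy of ``effect_allele``;
    ``eaf`` its frequency; ``info`` the imputation-quality r² — both
    optional (``None`` when unknown).
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float
    info: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(
                f"{self.snp_id}: effect allele {self.effect_allele!r} is not a single A/C/G/T base"
            )
        if self.other_allele not in VALID_ALLELES:
            raise ValueError(
                f"{self.snp_id}: other allele {self.other_allele!r} is not a single A/C/G/T base"
            )
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}: standard error must be positive, got {self.se}")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"{self.snp_id}: p-value must be in (0, 1], got {self.pvalue}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.snp_id}: eaf must be in [0, 1], got {self.eaf}")
        if self.info is not None and not (0.0 <= self.info <= 1.0):
            raise ValueError(f"{self.snp_id}: info must be in [0, 1], got {self.info}")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G variants, whose strand is ambiguous."""
        return COMPLEMENT[self.effect_allele] == self.other_allele

    def flipped(self) -> "SummaryRecord":
        """The same association expressed per copy of the other allele."""
        return SummaryRecord(
            snp_id=self.snp_id,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
            beta=-self.beta,
            se=self.se,
            pvalue=self.pvalue,
            info=self.info,
        )


@dataclass
class HarmonizedSet:
    """Paired exposure/outcome effects on a common effect-allele orientation.

    ``gamma``/``se_gamma`` are the exposure (instrument) effects,
    ``beta``/``se_beta`` the outcome effects, all aligned so the effect
    allele increases the exposure (every ``gamma`` > 0). ``drops`` maps
    each excluded SNP to the reason it was excluded.
    """

    snp_ids: list[str]
    gamma: np.ndarray
    se_gamma: np.ndarray
    beta: np.ndarray
    se_beta: np.ndarray
    drops: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.se_gamma = np.asarray(self.se_gamma, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.se_beta = np.asarray(self.se_beta, dtype=float)
        n = len(self.snp_ids)
        for name in ("gamma", "se_gamma", "beta", "se_beta"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have one entry per SNP")
        if np.any(self.se_gamma <= 0) or np.any(self.se_beta <= 0):
            raise ValueError("standard errors must be positive")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset(self, keep: Sequence[bool] | Sequence[int], drop_reason: str | None = None) -> "HarmonizedSet":
        """A new set restricted to ``keep``; removed SNPs are recorded
        under ``drop_reason`` when given."""
        idx = np.asarray(keep)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        idx = idx.astype(int)  # empty selections default to float64
        keep_ids = [self.snp_ids[i] for i in idx]
        drops = dict(self.drops)
        if drop_reason is not None:
            for sid in self.snp_ids:
                if sid not in set(keep_ids):
                    drops[sid] = drop_reason
        return HarmonizedSet(
            snp_ids=keep_ids,
            gamma=self.gamma[idx],
            se_gamma=self.se_gamma[idx],
            beta=self.beta[idx],
            se_beta=self.se_beta[idx],
            drops=drops,
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: one row per SNP (retained first, then dropped)."""
        retained = pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "gamma": self.gamma,
                "se_gamma": self.se_gamma,
                "beta": self.beta,
                "se_beta": self.se_beta,
                "drop_reason": "",
            }
        )
        if self.drops:
            dropped = pd.DataFrame(
                {
                    "snp_id": list(self.drops.keys()),
                    "gamma": np.nan,
                    "se_gamma": np.nan,
                    "beta": np.nan,
                    "se_beta": np.nan,
                    "drop_reason": list(self.drops.values()),
                }
            )
            return pd.concat([retained, dropped], ignore_index=True)
        return retained


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
) -> list[SummaryRecord]:
    """Read a tab-delimited summary-statistics table into records.

    ``column_map`` maps canonical names (``snp_id``, ``effect_allele``,
    ``other_allele``, ``eaf``, ``beta``, ``se``, ``pvalue``, ``info``)
    to the column names actually present in the file; unmapped names
    default to the canonical spelling. ``eaf`` and ``info`` columns are
    optional. gzip-compressed files (``.gz``) are accepted.

    Rows that violate record invariants (non-positive SE, identical or
    non-ACGT alleles such as indels, p outside (0,1]) are rejected with
    a logged reason rather than raising.
    """
    column_map = dict(column_map or {})
    names = {c: column_map.get(c, c) for c in CANONICAL_COLUMNS}
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = [names[c] for c in ("snp_id", "effect_allele", "other_allele", "beta", "se", "pvalue")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")

    def _optional(row, key):
        col = names[key]
        if col not in df.columns:
            return None
        raw = row[col]
        if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() in ("", ".", "NA", "nan"):
            return None
        return float(raw)

    records: list[SummaryRecord] = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        row = dict(zip(df.columns, row))
        try:
            numeric = {
                "eaf": _optional(row, "eaf"),
                "beta": float(row[names["beta"]]),
                "se": float(row[names["se"]]),
                "pvalue": float(row[names["pvalue"]]),
                "info": _optional(row, "info"),
            }
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}, line {pos}: unparseable numeric field ({exc})") from exc
        try:
            rec = SummaryRecord(
                snp_id=str(row[names["snp_id"]]).strip(),
                effect_allele=str(row[names["effect_allele"]]).strip().upper(),
                other_allele=str(row[names["other_allele"]]).strip().upper(),
                **numeric,
            )
        except ValueError as exc:
            logger.warning("%s, line %d: rejected row (%s)", path, pos, exc)
            continue
        records.append(rec)
    return records


def write_summary_stats(path, records: Iterable[SummaryRecord]) -> None:
    """Write records in the canonical tab-delimited dialect."""
    df = pd.DataFrame(
        [
            {
                "snp_id": r.snp_id,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": "" if r.eaf is None else repr(r.eaf),
                "beta": repr(r.beta),
                "se": repr(r.se),
                "pvalue": repr(r.pvalue),
                "info": "" if r.info is None else repr(r.info),
            }
            for r in records
        ],
        columns=list(CANONICAL_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def write_harmonized(path, hset: HarmonizedSet) -> None:
    """Serialize a HarmonizedSet as tab-delimited text (full precision)."""
    df = hset.to_frame()
    for col in ("gamma", "se_gamma", "beta", "se_beta"):
        df[col] = df[col].map(lambda x: "" if pd.isna(x) else repr(x))
    df.to_csv(path, sep="\t", index=False)


def read_harmonized(path) -> HarmonizedSet:
    """Inverse of :func:`write_harmonized`."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    df["drop_reason"] = df.get("drop_reason", pd.Series("", index=df.index)).fillna("")
    kept = df[df["drop_reason"] == ""]
    dropped = df[df["drop_reason"] != ""]
    return HarmonizedSet(
        snp_ids=kept["snp_id"].tolist(),
        gamma=kept["gamma"].to_numpy(float),
        se_gamma=kept["se_gamma"].to_numpy(float),
        beta=kept["beta"].to_numpy(float),
        se_beta=kept["se_beta"].to_numpy(float),
        drops=dict(zip(dropped["snp_id"], dropped["drop_reason"])),
    )


def _check_unique(records: Sequence[SummaryRecord], label: str) -> dict[str, SummaryRecord]:
    seen: dict[str, SummaryRecord] = {}
    for r in records:
        if r.snp_id in seen:
            raise ValueError(f"duplicate snp_id {r.snp_id!r} in {label} records")
        seen[r.snp_id] = r
    return seen


def _match_orientation(exp: SummaryRecord, out: SummaryRecord) -> tuple[SummaryRecord, bool] | None:
    """Align ``out`` onto ``exp``'s alleles; try a strand flip before
    declaring mismatch. Returns (aligned outcome record, strand_flipped)
    or None when the allele pairs are irreconcilable."""
    for flipped_strand, cand in ((False, out), (True, _strand_flip(out))):
        if (cand.effect_allele, cand.other_allele) == (exp.effect_allele, exp.other_allele):
            return cand, flipped_strand
        if (cand.other_allele, cand.effect_allele) == (exp.effect_allele, exp.other_allele):
            return cand.flipped(), flipped_strand
    return None


def _strand_flip(rec: SummaryRecord) -> SummaryRecord:
    return SummaryRecord(
        snp_id=rec.snp_id,
        effect_allele=COMPLEMENT[rec.effect_allele],
        other_allele=COMPLEMENT[rec.other_allele],
        eaf=rec.eaf,
        beta=rec.beta,
        se=rec.se,
        pvalue=rec.pvalue,
        info=rec.info,
    )


def harmonize(
    exposure: Sequence[SummaryRecord],
    outcome: Sequence[SummaryRecord],
    palindrome_policy: str = "infer_by_eaf",
    eaf_ambiguity_window: float = 0.08,
) -> HarmonizedSet:
    """Pair exposure and outcome records on a common allele orientation.

    Exposure records are first reoriented so every instrument effect is
    positive (effect allele = exposure-increasing allele). Outcome
    records are then aligned to the exposure alleles, negating the
    outcome effect when the allele labels are swapped and attempting an
    A<->T / C<->G strand flip before declaring a mismatch.

    Palindromic variants (A/T or C/G pairs), whose strand cannot be
    resolved from allele labels, are handled per ``palindrome_policy``:

    - ``"drop_ambiguous"``: drop every palindromic variant;
    - ``"infer_by_eaf"`` (default): orient by comparing which side of
      0.5 the two allele frequencies fall on, dropping the variant when
      either frequency is missing or lies within
      ``eaf_ambiguity_window`` of 0.5;
    - ``"keep"``: trust the allele labels at face value.
    """
    if palindrome_policy not in ("drop_ambiguous", "infer_by_eaf", "keep"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")
    exp_by_id = _check_unique(exposure, "exposure")
    out_by_id = _check_unique(outcome, "outcome")

    drops: dict[str, str] = {}
    ids: list[str] = []
    gamma, se_gamma, beta, se_beta = [], [], [], []

    for sid, exp in exp_by_id.items():
        if sid not in out_by_id:
            drops[sid] = "unmatched"
            continue
        out = out_by_id[sid]
        # orient the exposure so the effect allele increases the exposure
        if exp.beta < 0:
            exp = exp.flipped()

        if exp.is_palindromic:
            if palindrome_policy == "drop_ambiguous":
                drops[sid] = "palindromic"
                continue
            if palindrome_policy == "infer_by_eaf":
                if exp.eaf is None or out.eaf is None:
                    drops[sid] = "palindromic-missing-eaf"
                    logger.info("%s: palindromic with missing eaf, dropped", sid)
                    continue
                if (
                    abs(exp.eaf - 0.5) < eaf_ambiguity_window
                    or abs(out.eaf - 0.5) < eaf_ambiguity_window
                ):
                    drops[sid] = "palindromic-ambiguous"
                    continue
                aligned = _match_orientation(exp, out)
                if aligned is None:
                    drops[sid] = "allele-mismatch"
                    continue
                out_aligned = aligned[0]
                # frequency disagreement means the labels refer to
                # opposite strands: flip the outcome effect
                if (exp.eaf < 0.5) != (out_aligned.eaf < 0.5):
                    out_aligned = out_aligned.flipped()
                    out_aligned = _strand_flip(out_aligned)
                ids.append(sid)
                gamma.append(exp.beta)
                se_gamma.append(exp.se)
                beta.append(out_aligned.beta)
                se_beta.append(out_aligned.se)
                continue
            # "keep" falls through to plain allele matching

        aligned = _match_orientation(exp, out)
        if aligned is None:
            drops[sid] = "allele-mismatch"
            continue
        out_aligned, _ = aligned
        ids.append(sid)
        gamma.append(exp.beta)
        se_gamma.append(exp.se)
        beta.append(out_aligned.beta)
        se_beta.append(out_aligned.se)

    for sid in out_by_id:
        if sid not in exp_by_id:
            drops[sid] = "unmatched"

    if not ids:
        raise ValueError("no shared instruments between exposure and outcome")
    return HarmonizedSet(
        snp_ids=ids,
        gamma=np.array(gamma),
        se_gamma=np.array(se_gamma),
        beta=np.array(beta),
        se_beta=np.array(se_beta),
        drops=drops,
    )
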