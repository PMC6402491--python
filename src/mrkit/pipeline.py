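"""End-to-end orchestration: filters -> harmonization -> MR-PRESSO
exclusion -> estimation per outcome stratum -> reports.

The workflow mirrors the standard two-sample MR design for one exposure
GWAS against one or more outcome strata (e.g. overall / ER-positive /
ER-negative disease): significance filtering and LD pruning select the
instruments once from the exposure table; each stratum is harmonized
separately; pleiotropic outliers are identified once (on the first
stratum, by default the overall one) and the exclusion list is applied
to every stratum; IVW, heterogeneity and weighted-median estimates are
then computed per stratum, optionally repeated under an
imputation-quality sensitivity filter. Every dropped SNP appears
exactly once in an exclusions table with its stage and reason.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .estimators import HeterogeneityStats, MRResult, cochran_q, format_or, format_p, ivw, to_odds_ratio, weighted_median
from .gwas_io import HarmonizedSet, harmonize, read_summary_stats, write_harmonized
from .instruments import LDMatrix, compute_r2, filter_by_info, filter_by_pvalue, ld_prune, read_genotype_matrix
from .presso import PressoReport, run_presso, write_exclusions

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML via
    :meth:`from_yaml`."""

    exposure_path: str
    outcome_paths: dict[str, str]  # stratum label -> path
    output_dir: str
    ld_source: str | None = None
    ld_source_kind: str = "genotypes"  # genotypes | r2
    p_threshold: float = 5e-8
    ld_r2_threshold: float = 0.1
    min_info: float | None = None
    info_boundary_inclusive: bool = True
    palindrome_policy: str = "infer_by_eaf"
    eaf_ambiguity_window: float = 0.08
    presso_n_sim: int = 5000
    presso_seed: int = 0
    presso_alpha_level: float = 0.05
    presso_per_stratum: bool = False
    ivw_mode: str = "multiplicative_random"
    wm_n_boot: int = 1000
    wm_seed: int = 0
    column_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold <= 1.0):
            raise ValueError("p_threshold out of range")
        if not (0.0 <= self.ld_r2_threshold <= 1.0):
            raise ValueError("ld_r2_threshold out of range")
        if self.ld_source_kind not in ("genotypes", "r2"):
            raise ValueError(f"unknown ld_source_kind {self.ld_source_kind!r}")
        if not self.outcome_paths:
            raise ValueError("at least one outcome stratum is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class StratumResult:
    """Estimates for one outcome stratum (and its sensitivity re-run)."""

    label: str
    ivw: MRResult
    het: HeterogeneityStats | None
    wm: MRResult | None
    n_snps: int
    sensitivity: "StratumResult | None" = None


@dataclass
class AnalysisReport:
    strata: dict[str, StratumResult]
    presso: PressoReport | None
    counts: dict[str, int]  # stage -> instrument count
    exclusions: pd.DataFrame  # snp_id, stage, reason


def _estimate_stratum(hset: HarmonizedSet, config: PipelineConfig, label: str) -> StratumResult:
    res_ivw = to_odds_ratio(ivw(hset, mode=config.ivw_mode))
    het = cochran_q(hset) if hset.n_snps >= 2 else None
    wm = None
    if hset.n_snps >= 3:
        wm = to_odds_ratio(weighted_median(hset, n_boot=config.wm_n_boot, seed=config.wm_seed))
    return StratumResult(label=label, ivw=res_ivw, het=het, wm=wm, n_snps=hset.n_snps)


def run(config: PipelineConfig) -> AnalysisReport:
    """Execute the full workflow and write all outputs to
    ``config.output_dir``. Identical config (including seeds) produces
    byte-identical output files."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    exclusions: list[tuple[str, str, str]] = []  # snp_id, stage, reason
    counts: dict[str, int] = {}

    try:
        exposure = read_summary_stats(config.exposure_path, config.column_map)
    except Exception as exc:
        raise RuntimeError(f"stage read_exposure: {exc}") from exc
    counts["initial"] = len(exposure)

    significant = filter_by_pvalue(exposure, config.p_threshold)
    significant_ids = {r.snp_id for r in significant}
    for rec in exposure:
        if rec.snp_id not in significant_ids:
            exclusions.append((rec.snp_id, "significance", f"p >= {config.p_threshold:g}"))
    counts["post_significance"] = len(significant)
    if not significant:
        raise RuntimeError("stage significance: empty instrument set")

    if config.ld_source is not None:
        try:
            if config.ld_source_kind == "genotypes":
                genotypes, ids = read_genotype_matrix(config.ld_source)
                ld = compute_r2(genotypes, ids)
            else:
                ld = LDMatrix.from_tsv(config.ld_source)
            pruned = ld_prune(significant, ld, config.ld_r2_threshold)
        except Exception as exc:
            raise RuntimeError(f"stage ld_prune: {exc}") from exc
        kept_ids = {r.snp_id for r in pruned}
        for rec in significant:
            if rec.snp_id not in kept_ids:
                exclusions.append((rec.snp_id, "ld_prune", f"r2 > {config.ld_r2_threshold:g} with a more significant SNP"))
        significant = pruned
    counts["post_ld"] = len(significant)
    if not significant:
        raise RuntimeError("stage ld_prune: empty instrument set")

    # harmonize each stratum against the selected instruments
    harmonized: dict[str, HarmonizedSet] = {}
    outcome_info: dict[str, dict[str, float | None]] = {}
    for label, path in config.outcome_paths.items():
        try:
            outcome = read_summary_stats(path, config.column_map)
            hset = harmonize(significant, outcome, config.palindrome_policy, config.eaf_ambiguity_window)
        except Exception as exc:
            raise RuntimeError(f"stage harmonize[{label}]: {exc}") from exc
        harmonized[label] = hset
        outcome_info[label] = {r.snp_id: r.info for r in outcome}
        for sid, reason in hset.drops.items():
            exclusions.append((sid, f"harmonize[{label}]", reason))
        write_harmonized(out_dir / f"harmonized_{label}.tsv", hset)
    first_label = next(iter(config.outcome_paths))
    counts["post_harmonize"] = harmonized[first_label].n_snps

    # MR-PRESSO exclusion: computed once on the first (overall) stratum
    # and applied to all strata, unless presso_per_stratum is set
    presso_report: PressoReport | None = None
    if config.presso_n_sim > 0:
        try:
            presso_report = run_presso(
                harmonized[first_label],
                n_sim=config.presso_n_sim,
                seed=config.presso_seed,
                alpha_level=config.presso_alpha_level,
            )
        except Exception as exc:
            raise RuntimeError(f"stage presso: {exc}") from exc
        flagged = set(presso_report.outlier_ids)
        write_exclusions(out_dir / "presso_exclusions.txt", presso_report.outlier_ids)
        for sid in presso_report.outlier_ids:
            exclusions.append((sid, "presso", "horizontally pleiotropic outlier"))
        for label in list(harmonized):
            if config.presso_per_stratum and label != first_label:
                rep = run_presso(harmonized[label], n_sim=config.presso_n_sim,
                                 seed=config.presso_seed, alpha_level=config.presso_alpha_level)
                drop = set(rep.outlier_ids)
            else:
                drop = flagged
            keep = [sid not in drop for sid in harmonized[label].snp_ids]
            harmonized[label] = harmonized[label].subset(keep)
            if not harmonized[label].n_snps:
                raise RuntimeError(f"stage presso[{label}]: empty instrument set")
    counts["post_presso"] = harmonized[first_label].n_snps

    strata: dict[str, StratumResult] = {}
    for label, hset in harmonized.items():
        try:
            result = _estimate_stratum(hset, config, label)
        except Exception as exc:
            raise RuntimeError(f"stage estimate[{label}]: {exc}") from exc
        if config.min_info is not None:
            filtered = filter_by_info(
                hset, config.min_info, outcome_info[label],
                boundary_inclusive=config.info_boundary_inclusive,
            )
            for sid, reason in filtered.drops.items():
                if reason == "low-info":
                    exclusions.append((sid, f"info[{label}]", f"info < {config.min_info:g}"))
            if not filtered.n_snps:
                raise RuntimeError(f"stage info[{label}]: empty instrument set")
            result.sensitivity = _estimate_stratum(filtered, config, f"{label} (info filtered)")
            if label == first_label:
                counts["post_info"] = filtered.n_snps
        strata[label] = result

    excl_df = pd.DataFrame(exclusions, columns=["snp_id", "stage", "reason"])
    excl_df = excl_df.drop_duplicates(subset=["snp_id"], keep="first")
    report = AnalysisReport(strata=strata, presso=presso_report, counts=counts, exclusions=excl_df)

    order = ["initial", "post_significance", "post_ld", "post_harmonize", "post_presso", "post_info"]
    chain = [counts[k] for k in order if k in counts]
    assert all(a >= b for a, b in zip(chain[1:], chain[2:])), "stage counts must be non-increasing"

    render_report(report, out_dir, fmt="tsv")
    render_report(report, out_dir, fmt="text-table")
    excl_df.to_csv(out_dir / "exclusions.tsv", sep="\t", index=False)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report_to_dict(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _result_rows(sr: StratumResult) -> list[dict[str, str]]:
    rows = []
    for res, het in ((sr.ivw, sr.het), (sr.wm, None)):
        if res is None:
            rows.append({"method": "weighted_median", "or_ci": "NA", "p": "NA", "p_het": "-", "i2": "-"})
            continue
        rows.append(
            {
                "method": res.method,
                "or_ci": format_or(res),
                "p": format_p(res.pvalue),
                "p_het": format_p(het.p_het) if het is not None else "-",
                "i2": f"{het.i2:.0f}%" if het is not None else "-",
            }
        )
    return rows


def render_report(report: AnalysisReport, out_dir, fmt: str = "tsv") -> list[Path]:
    """Write one Method / OR (95% CI) / p / p_het / I² table per stratum
    plus a combined file; ``fmt`` is ``"tsv"`` or ``"text-table"``."""
    if fmt not in ("tsv", "text-table"):
        raise ValueError(f"unknown format {fmt!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    combined: list[str] = []
    header = ["stratum", "method", "or_95ci", "p", "p_het", "i2", "n_snps"]
    for label, sr in report.strata.items():
        lines = ["\t".join(header)]
        for tag, block in (("", sr), ("info>=filter", sr.sensitivity)):
            if block is None:
                continue
            stratum = label if not tag else f"{label}|sensitivity"
            for row in _result_rows(block):
                lines.append("\t".join([stratum, row["method"], row["or_ci"], row["p"],
                                        row["p_het"], row["i2"], str(block.n_snps)]))
        body = "\n".join(lines) + "\n"
        if fmt == "tsv":
            path = out_dir / f"report_{label}.tsv"
            path.write_text(body)
            written.append(path)
        combined.extend(lines[1:] if combined else lines)
    if fmt == "tsv":
        path = out_dir / "report_combined.tsv"
        path.write_text("\n".join(combined) + "\n")
        written.append(path)
    else:
        path = out_dir / "report.txt"
        widths = [max(len(r.split("\t")[i]) for r in combined) for i in range(len(header))]
        pretty = [
            "  ".join(cell.ljust(w) for cell, w in zip(line.split("\t"), widths))
            for line in combined
        ]
        path.write_text("\n".join(pretty) + "\n")
        written.append(path)
    return written


def _mr_to_dict(res: MRResult | None) -> dict | None:
    if res is None:
        return None
    d = {
        "method": res.method,
        "alpha": res.alpha,
        "se_alpha": res.se_alpha,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "pvalue": res.pvalue,
        "n_snps": res.n_snps,
    }
    if res.or_scale is not None:
        d["or"], d["or_ci_low"], d["or_ci_high"] = res.or_scale
    return d


def report_to_dict(report: AnalysisReport) -> dict:
    """Structured key-value form of the report (machine-readable)."""
    def stratum(sr: StratumResult | None):
        if sr is None:
            return None
        return {
            "n_snps": sr.n_snps,
            "ivw": _mr_to_dict(sr.ivw),
            "weighted_median": _mr_to_dict(sr.wm),
            "heterogeneity": None
            if sr.het is None
            else {"q": sr.het.q, "df": sr.het.df, "p_het": sr.het.p_het, "i2": sr.het.i2},
            "sensitivity": stratum(sr.sensitivity),
        }

    return {
        "counts": report.counts,
        "strata": {label: stratum(sr) for label, sr in report.strata.items()},
        "presso": None
        if report.presso is None
        else {
            "global_rss_obs": report.presso.global_rss_obs,
            "global_p": report.presso.global_p,
            "outlier_ids": report.presso.outlier_ids,
            "distortion_p": report.presso.distortion_p,
            "n_sim": report.presso.n_sim,
            "seed": report.presso.seed,
        },
    }
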