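"""End-to-end pipeline: validate -> score -> norm -> classify -> statistics.

``run_pipeline`` is the single entry point behind the command-line
interface and the acceptance machinery.  Outputs are a pure function of
the input table and the configuration; every run writes a provenance
block (resolved configuration, package version, norm source) alongside
the numerical results.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import __version__
from .io import attach_scores, read_cohort_csv, read_json, write_json
from .cohort_stats import (
    item_summaries,
    item_total_correlations,
    mean_sd_correlation,
    self_smell_correlations,
    sex_comparison,
)
from .profiling import CohortThresholds, classify_cohort, derive_thresholds, profile_census

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    input_path: str
    output_dir: str
    norms_path: Optional[str] = None  # None -> derive norms from this cohort
    sd_convention: str = "sample"     # "sample" (n-1) or "population"
    t_test: str = "student"           # "student" or "welch"
    by_sex_census: bool = True
    run_stats: bool = True
    families: dict = field(default_factory=dict)  # per-battery Bonferroni sizes

    def __post_init__(self) -> None:
        if self.sd_convention not in ("sample", "population"):
            raise ValueError("sd_convention must be 'sample' or 'population'")
        if self.t_test not in ("student", "welch"):
            raise ValueError("t_test must be 'student' or 'welch'")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Writes ``profiles.csv`` (per-respondent scores, bands and labels),
    ``thresholds.json`` (the norms used, with provenance), ``census.csv``
    and, when statistics are enabled, ``item_summaries.csv``,
    ``item_total_correlations.csv``, ``sex_comparison.csv``,
    ``self_smell.csv`` and a human-readable ``summary.txt``.  Returns the
    bundle as in-memory objects keyed by the same names.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cohort = read_cohort_csv(config.input_path)
    if cohort.empty:
        raise ValueError("empty cohort")
    scored = attach_scores(cohort)

    ddof = 1 if config.sd_convention == "sample" else 0
    if config.norms_path is None:
        thresholds = derive_thresholds(scored, ddof=ddof)
        norm_source = f"derived from {config.input_path} ({config.sd_convention} SD)"
    else:
        thresholds = CohortThresholds.from_dict(read_json(config.norms_path))
        norm_source = f"loaded from {config.norms_path} (external reference cohort)"

    labeled = classify_cohort(scored, thresholds)
    census = profile_census(labeled, thresholds, by_sex=config.by_sex_census)

    profile_cols = ["id", "sex", "ts", "t_plus", "t_minus", "delta",
                    "ts_band", "tp_band", "tm_band", "profile"]
    labeled.loc[:, profile_cols].to_csv(out_dir / "profiles.csv", index=False)
    provenance = {
        "package": "ohp", "version": __version__,
        "norm_source": norm_source, "config": asdict(config),
    }
    write_json({**thresholds.to_dict(), "provenance": provenance},
               out_dir / "thresholds.json")
    census.to_csv(out_dir / "census.csv")

    bundle: dict = {
        "profiles": labeled, "thresholds": thresholds, "census": census,
        "provenance": provenance,
    }

    if config.run_stats:
        summaries = item_summaries(cohort, ddof=ddof)
        summaries.to_csv(out_dir / "item_summaries.csv", index=False)
        itc = item_total_correlations(
            scored, family_size=config.families.get("item_total"))
        itc.to_csv(out_dir / "item_total_correlations.csv", index=False)
        bundle["item_summaries"] = summaries
        bundle["item_total_correlations"] = itc
        bundle["mean_sd_correlation"] = mean_sd_correlation(summaries)
        sexes = set(cohort["sex"])
        if {"M", "F"} <= sexes and (cohort["sex"] == "M").sum() >= 2 \
                and (cohort["sex"] == "F").sum() >= 2:
            sc = sex_comparison(scored, welch=config.t_test == "welch",
                                family_size=config.families.get("sex"))
            sc.to_csv(out_dir / "sex_comparison.csv", index=False)
            bundle["sex_comparison"] = sc
        if cohort["self_smell"].notna().sum() >= 3:
            ssc = self_smell_correlations(
                scored, family_size=config.families.get("self_smell"))
            ssc.to_csv(out_dir / "self_smell.csv", index=False)
            bundle["self_smell"] = ssc

    (out_dir / "summary.txt").write_text(_summary_text(bundle), encoding="utf-8")
    return bundle


def _summary_text(bundle: dict) -> str:
    th: CohortThresholds = bundle["thresholds"]
    census: pd.DataFrame = bundle["census"]
    n = int(census["count"].sum())
    lines = [
        f"Odor Hedonic Profile report (ohp {__version__})",
        f"Norms: {bundle['provenance']['norm_source']}",
        "",
        f"Cohort size: {n}",
        "Banding cutoffs (mean +/- SD of the reference cohort):",
        f"  TS  high > {th.ts_hi:.2f}, medium {th.ts_lo:.2f}..{th.ts_hi:.2f}, low < {th.ts_lo:.2f}",
        f"  T+  high > {th.tp_hi:.2f}, medium {th.tp_lo:.2f}..{th.tp_hi:.2f}, low < {th.tp_lo:.2f}",
        f"  T-  high < {th.tm_hi:.2f}, medium {th.tm_hi:.2f}..{th.tm_lo:.2f}, low > {th.tm_lo:.2f}",
        "",
        "Profile census:",
    ]
    for label, row in census.iterrows():
        extras = [f"{c.removeprefix('count_')}: {int(row[c])}"
                  for c in census.columns if c.startswith("count_")]
        suffix = f" ({', '.join(extras)})" if extras else ""
        lines.append(f"  {label:<24s} {int(row['count']):>4d}{suffix}")
    if "mean_sd_correlation" in bundle:
        r = bundle["mean_sd_correlation"]
        lines += ["", f"|item mean| vs item SD Spearman rho = {r.rho:.3f} "
                      f"(p = {r.p_raw:.3g}, n = {r.n} items)"]
    return "\n".join(lines) + "\n"
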