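"""End-to-end orchestration: trials in, full result bundle out."""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig, simulate_cohort
from .inference import (
    cellwise_posthoc,
    describe,
    group_contrast,
    mixed_anova,
    variance_ratio,
    welch_t,
)
from .io import TrialTableDialect, read_trials, write_trials
from .preprocessing import arcsin_transform, flag_exclusions, summarize_conditions
from .reliability import reliability_table, split_half_reliability_all
from .scoring import composite_scores, fit_standardization, network_differences

log = logging.getLogger("antnet")


@dataclass
class RunConfig:
    seed: int = 0
    rt_lower_ms: float = 200.0
    rt_upper_ms: float = 1700.0
    exclusion_scope: str = "both"
    z_scope: str = "pooled"
    split: str = "stratified"
    n_permutations: int = 1000
    tails: str = "two"
    out_dir: str = "ant_run"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 < self.rt_lower_ms < self.rt_upper_ms):
            raise ValueError("exclusion bounds must satisfy 0 < lower < upper")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def run_pipeline(
    config: RunConfig,
    trials: pd.DataFrame | None = None,
    trials_path=None,
    dialect: TrialTableDialect | None = None,
) -> dict:
    """Run exclusion, scoring, reliability and inference; write all artifacts.

    Returns the bundle as a dict of in-memory objects; everything is also
    written under ``config.out_dir`` (CSV tables, a JSON stats file, a
    plain-text report, and a reproducibility manifest).
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if trials is None:
        if trials_path is None:
            log.info("no input trials: simulating a default synthetic cohort")
            trials = simulate_cohort(CohortConfig(seed=config.seed))
            write_trials(trials, out / "trials_synthetic.csv")
        else:
            trials = read_trials(trials_path, dialect)

    flagged, report = flag_exclusions(trials, config.rt_lower_ms, config.rt_upper_ms)
    summary = summarize_conditions(flagged, exclusion_scope=config.exclusion_scope)
    diffs = network_differences(summary)
    ctx = fit_standardization(diffs, scope=config.z_scope)
    scores = composite_scores(diffs, ctx)

    estimates = split_half_reliability_all(
        flagged, n_permutations=config.n_permutations, seed=config.seed, split=config.split
    )
    rel = reliability_table(estimates)

    overall = summary.loc[summary["margin"] == "overall"]
    groups = sorted(overall["group"].unique())
    stats_out: dict = {"groups": {}}
    for grp in groups:
        sub = overall.loc[overall["group"] == grp]
        stats_out["groups"][grp] = {
            "median_rt": asdict(describe(sub["median_rt_ms"].dropna())),
            "pe_pct": asdict(describe(100.0 * sub["pe"].dropna())),
        }
    if len(groups) == 2:
        a = overall.loc[overall["group"] == groups[0]]
        b = overall.loc[overall["group"] == groups[1]]
        stats_out["overall_rt_welch"] = welch_t(
            a["median_rt_ms"].dropna(), b["median_rt_ms"].dropna(), tails=config.tails
        ).__dict__
        stats_out["overall_ape_welch"] = welch_t(
            arcsin_transform(a["pe"].dropna().to_numpy()),
            arcsin_transform(b["pe"].dropna().to_numpy()),
            tails=config.tails,
        ).__dict__
        stats_out["overall_rt_variance_ratio"] = variance_ratio(
            a["median_rt_ms"].dropna(), b["median_rt_ms"].dropna()
        )
        anova = mixed_anova(scores)
        stats_out["mixed_anova"] = anova.table.to_dict(orient="records")
        stats_out["mauchly"] = anova.mauchly.__dict__ if anova.mauchly else None
        stats_out["gg_epsilon"] = anova.gg_epsilon
        stats_out["group_contrast"] = group_contrast(anova, tails=config.tails).__dict__
        stats_out["posthoc"] = [
            c.__dict__ for c in cellwise_posthoc(anova, tails=config.tails)
        ]

    # ---- write artifacts
    summary.to_csv(out / "condition_summaries.csv", index=False)
    scores.to_csv(out / "network_scores.csv", index=False)
    rel.to_csv(out / "reliability.csv", index=False)
    report.per_participant_pct.rename("pct_excluded").to_csv(out / "exclusions_by_participant.csv")
    with open(out / "stats.json", "w") as fh:
        json.dump(stats_out, fh, indent=2, default=float)
    manifest = {
        "antnet_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": asdict(config),
        "n_trials": int(len(trials)),
        "n_participants": int(trials["participant_id"].nunique()),
        "pct_excluded": report.pct_excluded,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    with open(out / "report.txt", "w") as fh:
        fh.write(_text_report(report, rel, stats_out))

    return {
        "trials": flagged,
        "exclusions": report,
        "summary": summary,
        "scores": scores,
        "reliability": rel,
        "stats": stats_out,
        "manifest": manifest,
    }


def _fmt_t(d: dict) -> str:
    return f"t({d['df']:.2f}) = {d['t']:.2f}, p = {d['p']:.3f}, d = {d['d']:.2f}"


def _text_report(report, rel: pd.DataFrame, stats_out: dict) -> str:
    lines = ["ANT analysis report", "===================", ""]
    lines.append(
        f"Excluded {report.n_excluded} of {report.n_test_trials} test trials "
        f"({report.pct_excluded:.2f}%): {report.by_reason}"
    )
    lines.append("")
    lines.append("Split-half reliability (Spearman-Brown corrected, mean over permutations):")
    for _, row in rel.iterrows():
        lines.append(
            f"  {row['network']:<10s} {row['measure']:<10s} r = {row['mean_r']:.3f} "
            f"[{row['ci_low']:.3f}, {row['ci_high']:.3f}]"
        )
    if "overall_rt_welch" in stats_out:
        lines.append("")
        lines.append("Overall RT:  " + _fmt_t(stats_out["overall_rt_welch"]))
        lines.append("Overall APE: " + _fmt_t(stats_out["overall_ape_welch"]))
    if "mixed_anova" in stats_out:
        lines.append("")
        lines.append("Mixed ANOVA (group x network, composite scores):")
        eps = stats_out["gg_epsilon"]
        for row in stats_out["mixed_anova"]:
            if row["effect"] == "group":
                lines.append(
                    f"  group:         F({row['df1']:.0f}, {row['df2']:.0f}) = {row['F']:.2f}, "
                    f"p = {row['p']:.3f}, ges = {row['ges']:.2f}"
                )
            else:
                lines.append(
                    f"  {row['effect']:<14s} F({row['df1'] * eps:.2f}, {row['df2'] * eps:.2f}) = "
                    f"{row['F']:.2f}, p_GG = {row['p_gg']:.3f}, ges = {row['ges']:.2f}"
                )
        m = stats_out.get("mauchly")
        if m:
            lines.append(
                f"  Mauchly: W = {m['W']:.3f}, chi2({m['df']}) = {m['chi2']:.2f}, p = {m['p']:.3f}; "
                f"GG epsilon = {eps:.3f}"
            )
        gc = stats_out["group_contrast"]
        lines.append(
            f"  group contrast: t({gc['df']:.0f}) = {gc['t']:.2f}, p = {gc['p']:.3f}"
        )
        for c in stats_out["posthoc"]:
            lines.append(
                f"  {c['label']:<28s} t({c['df']:.2f}) = {c['t']:.2f}, p_holm = {c['p_holm']:.3f}"
            )
    lines.append("")
    return "\n".join(lines)
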