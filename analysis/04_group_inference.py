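"""Group comparisons: overall speed/accuracy, mixed ANOVA, post hocs, influence.

Compares the two groups on overall median RT and (arcsin-transformed)
error proportion with Welch tests and Holm correction, runs the
2 (group) x 3 (network) mixed ANOVA on the composites with sphericity
machinery and generalized eta squared, follows up with pooled-error
contrasts, and screens participant-average composites for influential
cases with Cook's D. Writes results/group_inference.json and a readable
report.
"""

import argparse
import importlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from antnet.inference import (
    cellwise_posthoc,
    cooks_screen,
    describe,
    group_contrast,
    holm_adjust,
    mixed_anova,
    recommended_p,
    variance_ratio,
    welch_t,
)
from antnet.preprocessing import arcsin_transform, flag_exclusions, summarize_conditions
from antnet.scoring import score_trials

ROOT = Path(__file__).resolve().parents[1]
load_trials = importlib.import_module("02_score_networks").load_trials


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()

    trials = load_trials(args.seed)
    flagged, _ = flag_exclusions(trials)
    summary = summarize_conditions(flagged)
    overall = summary.loc[summary["margin"] == "overall"]
    gift = overall.loc[overall["group"] == "gifted"]
    avg = overall.loc[overall["group"] == "average"]

    out: dict = {"descriptives": {}}
    for lab, sub in (("gifted", gift), ("average", avg)):
        out["descriptives"][lab] = {
            "median_rt": asdict(describe(sub["median_rt_ms"])),
            "pe_pct": asdict(describe(100 * sub["pe"])),
            "ape": asdict(describe(arcsin_transform(sub["pe"].to_numpy()))),
        }
    rt_test = welch_t(gift["median_rt_ms"], avg["median_rt_ms"])
    ape_test = welch_t(
        arcsin_transform(gift["pe"].to_numpy()), arcsin_transform(avg["pe"].to_numpy())
    )
    holm = holm_adjust([rt_test.p, ape_test.p])
    out["overall"] = {
        "rt": {**rt_test.__dict__, "p_holm": holm[0]},
        "ape": {**ape_test.__dict__, "p_holm": holm[1]},
        "rt_variance_ratio": variance_ratio(gift["median_rt_ms"], avg["median_rt_ms"]),
    }

    scores = score_trials(flagged)
    anova = mixed_anova(scores)
    out["anova"] = anova.table.to_dict(orient="records")
    out["mauchly"] = anova.mauchly.__dict__
    out["gg_epsilon"] = anova.gg_epsilon
    out["interaction_p_recommended"] = recommended_p(anova, "group:network")
    out["group_contrast"] = group_contrast(anova).__dict__
    out["posthoc"] = [c.__dict__ for c in cellwise_posthoc(anova)]

    subj = scores.groupby(["participant_id", "group"])["composite"].mean().reset_index()
    cooks = cooks_screen(
        subj["composite"].to_numpy(), (subj["group"] == "average").to_numpy(dtype=float)
    )
    out["cooks"] = {
        "cutoff": cooks.cutoff,
        "max_d": float(cooks.d.max()),
        "n_flagged": int(cooks.flagged.size),
    }

    (ROOT / "results").mkdir(exist_ok=True)
    with open(ROOT / "results" / "group_inference.json", "w") as fh:
        json.dump(out, fh, indent=2, default=float)

    tab = anova.table.set_index("effect")
    print(f"overall RT:  t({rt_test.df:.2f}) = {rt_test.t:.2f}, p_holm = {holm[0]:.3f}, d = {rt_test.d:.2f}")
    print(f"overall APE: t({ape_test.df:.2f}) = {ape_test.t:.2f}, p_holm = {holm[1]:.3f}, d = {ape_test.d:.2f}")
    print(
        f"group:       F({tab.loc['group','df1']:.0f}, {tab.loc['group','df2']:.0f}) = "
        f"{tab.loc['group','F']:.2f}, p = {tab.loc['group','p']:.3f}, ges = {tab.loc['group','ges']:.3f}"
    )
    eps = anova.gg_epsilon
    print(
        f"interaction: F({2 * eps:.2f}, {tab.loc['group:network','df2'] * eps:.2f}) = "
        f"{tab.loc['group:network','F']:.2f}, p_GG = {tab.loc['group:network','p_gg']:.3f}"
    )
    for c in out["posthoc"]:
        print(f"  {c['label']:<28s} t({c['df']:.2f}) = {c['t']:.2f}, p_holm = {c['p_holm']:.4f}")
    print(
        f"Cook's D: max {out['cooks']['max_d']:.3f} vs cutoff {out['cooks']['cutoff']:.3f} "
        f"({out['cooks']['n_flagged']} flagged)"
    )


if __name__ == "__main__":
    main()
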