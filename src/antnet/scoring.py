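"""Attentional network scores: subtraction effects and speed–accuracy composites.

Three networks are isolated by condition subtraction on each participant's
condition summaries, in both median RT (ms) and proportion of errors
(percentage points):

* alerting  = no-cue − double-cue        (benefit of a temporal warning)
* orienting = central-cue − spatial-cue  (benefit of spatial information)
* executive = incongruent − congruent    (cost of response conflict)

The composite per network averages the z-scored RT and PE differences, a
variant of the balanced integration score. Standardisation moments are, by
default, pooled over the full stack of participants x networks separately
for each measure: z-scoring each network on its own would force every
network's cohort mean to zero and destroy the between-network ordering the
composite is meant to express. Higher composite = worse performance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import CUE_MARGIN, FLANKER_MARGIN, flag_exclusions, summarize_conditions

NETWORKS = ("alerting", "orienting", "executive")

#: network -> (margin, minuend cell, subtrahend cell)
_CONTRASTS = {
    "alerting": (CUE_MARGIN, "none", "double"),
    "orienting": (CUE_MARGIN, "central", "spatial"),
    "executive": (FLANKER_MARGIN, "incongruent", "congruent"),
}


@dataclass(frozen=True)
class StandardizationContext:
    """Pooled moments used to z-score the raw difference scores."""

    rt_mean: float
    rt_sd: float
    pe_mean: float
    pe_sd: float
    scope: str = "pooled"
    per_network: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scope == "pooled" and not (self.rt_sd > 0 and self.pe_sd > 0):
            raise ValueError("degenerate sample: zero pooled SD")


def network_differences(summary: pd.DataFrame) -> pd.DataFrame:
    """Raw per-participant difference scores for the three networks.

    ``summary`` is the long condition-summary table. Returns one row per
    participant x network with ``rt_diff_ms`` and ``pe_diff`` (percentage
    points). A participant missing a needed cell gets NaN for the affected
    scores.
    """
    groups = summary.drop_duplicates("participant_id").set_index("participant_id")["group"]
    rt_wide = summary.pivot_table(
        index="participant_id", columns="cell", values="median_rt_ms", aggfunc="first"
    )
    pe_wide = summary.pivot_table(
        index="participant_id", columns="cell", values="pe", aggfunc="first"
    )
    pieces = []
    for network, (_margin, hi, lo) in _CONTRASTS.items():
        rt_hi = rt_wide[hi] if hi in rt_wide else pd.Series(np.nan, index=rt_wide.index)
        rt_lo = rt_wide[lo] if lo in rt_wide else pd.Series(np.nan, index=rt_wide.index)
        pe_hi = pe_wide[hi] if hi in pe_wide else pd.Series(np.nan, index=pe_wide.index)
        pe_lo = pe_wide[lo] if lo in pe_wide else pd.Series(np.nan, index=pe_wide.index)
        pieces.append(
            pd.DataFrame(
                {
                    "participant_id": rt_wide.index,
                    "group": groups.reindex(rt_wide.index).to_numpy(),
                    "network": network,
                    "rt_diff_ms": (rt_hi - rt_lo).to_numpy(),
                    "pe_diff": 100.0 * (pe_hi - pe_lo).to_numpy(),
                }
            )
        )
    return pd.concat(pieces, ignore_index=True)


def fit_standardization(differences: pd.DataFrame, scope: str = "pooled") -> StandardizationContext:
    """Estimate z-scoring moments from the cohort's difference scores.

    ``scope='pooled'`` (default) stacks all participants and all three
    networks per measure; ``scope='per_network'`` standardises each network
    over participants separately.
    """
    if differences["participant_id"].nunique() < 2:
        raise ValueError("need at least 2 participants to standardise")
    if scope == "pooled":
        rt = differences["rt_diff_ms"].dropna()
        pe = differences["pe_diff"].dropna()
        ctx = StandardizationContext(
            rt_mean=float(rt.mean()),
            rt_sd=float(rt.std(ddof=1)),
            pe_mean=float(pe.mean()),
            pe_sd=float(pe.std(ddof=1)),
            scope="pooled",
        )
        return ctx
    if scope == "per_network":
        per = differences.groupby("network")[["rt_diff_ms", "pe_diff"]].agg(["mean", "std"])
        if (per.xs("std", axis=1, level=1) <= 0).any().any():
            raise ValueError("degenerate sample: zero SD in some network")
        return StandardizationContext(
            rt_mean=np.nan, rt_sd=np.nan, pe_mean=np.nan, pe_sd=np.nan,
            scope="per_network", per_network=per,
        )
    raise ValueError("scope must be 'pooled' or 'per_network'")


def composite_scores(
    differences: pd.DataFrame, context: StandardizationContext
) -> pd.DataFrame:
    """Attach z components and the speed–accuracy composite per network."""
    out = differences.copy()
    if context.scope == "pooled":
        out["z_rt"] = (out["rt_diff_ms"] - context.rt_mean) / context.rt_sd
        out["z_pe"] = (out["pe_diff"] - context.pe_mean) / context.pe_sd
    else:
        per = context.per_network
        rt_m = out["network"].map(per[("rt_diff_ms", "mean")])
        rt_s = out["network"].map(per[("rt_diff_ms", "std")])
        pe_m = out["network"].map(per[("pe_diff", "mean")])
        pe_s = out["network"].map(per[("pe_diff", "std")])
        out["z_rt"] = (out["rt_diff_ms"] - rt_m) / rt_s
        out["z_pe"] = (out["pe_diff"] - pe_m) / pe_s
    out["composite"] = (out["z_rt"] + out["z_pe"]) / 2.0
    return out


def score_trials(
    trials: pd.DataFrame, z_scope: str = "pooled", exclusion_scope: str = "both"
) -> pd.DataFrame:
    """Trials -> network scores in one call (exclusions, summaries, composites)."""
    if "excluded" not in trials.columns:
        trials, _ = flag_exclusions(trials)
    summary = summarize_conditions(trials, exclusion_scope=exclusion_scope)
    diffs = network_differences(summary)
    ctx = fit_standardization(diffs, scope=z_scope)
    return composite_scores(diffs, ctx)
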