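"""Trial exclusion rules and per-participant condition summaries.

Median RT is computed over retained correct trials only; the proportion of
errors (PE) over retained trials. Trials are excluded when the RT falls
outside the 200–1,700 ms window (strict inequalities: the boundary values
are retained), when no response occurred before the deadline (timeout), or
when the trial was practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RT_LOWER_MS = 200.0
RT_UPPER_MS = 1700.0

#: exclusion reasons, mutually exclusive, in precedence order
EXCLUSION_REASONS = ("practice", "timeout", "too_fast", "too_slow")

CUE_MARGIN = "cue"
FLANKER_MARGIN = "flanker"
OVERALL = "overall"


@dataclass(frozen=True)
class ExclusionReport:
    """Counts of excluded test trials and the headline exclusion percentage."""

    n_test_trials: int
    n_excluded: int
    by_reason: dict[str, int]
    per_participant_pct: pd.Series

    @property
    def pct_excluded(self) -> float:
        """Percent of test trials excluded (out-of-range RTs and timeouts)."""
        if self.n_test_trials == 0:
            return float("nan")
        return 100.0 * self.n_excluded / self.n_test_trials


def flag_exclusions(
    trials: pd.DataFrame,
    lower_ms: float = RT_LOWER_MS,
    upper_ms: float = RT_UPPER_MS,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Mark practice, timeout and extreme-RT trials; idempotent.

    Returns a copy of the table with ``excluded`` / ``exclusion_reason``
    columns plus a report. RTs are excluded strictly below ``lower_ms`` or
    strictly above ``upper_ms``; a missing RT is a timeout and is scored as
    an error.
    """
    _validate_trials(trials)
    df = trials.copy()
    rt = pd.to_numeric(df["rt_ms"], errors="coerce").to_numpy(dtype=float)
    finite = rt[np.isfinite(rt)]
    if finite.size and finite.min() < 0:
        raise ValueError("rt_ms must be nonnegative where present")

    practice = (
        df["is_practice"].astype(bool).to_numpy()
        if "is_practice" in df.columns
        else np.zeros(len(df), dtype=bool)
    )
    timeout = np.isnan(rt) & ~practice
    too_fast = (rt < lower_ms) & ~practice
    too_slow = (rt > upper_ms) & ~practice

    reason = np.full(len(df), "none", dtype=object)
    reason[too_slow] = "too_slow"
    reason[too_fast] = "too_fast"
    reason[timeout] = "timeout"
    reason[practice] = "practice"

    df["excluded"] = reason != "none"
    df["exclusion_reason"] = reason
    if timeout.any():
        df.loc[timeout, "accuracy"] = 0

    test = df.loc[~practice]
    dropped = test["excluded"]
    by_reason = {
        r: int((test["exclusion_reason"] == r).sum())
        for r in ("timeout", "too_fast", "too_slow")
    }
    per_part = 100.0 * test.groupby("participant_id", sort=False)["excluded"].mean()
    report = ExclusionReport(
        n_test_trials=int(len(test)),
        n_excluded=int(dropped.sum()),
        by_reason=by_reason,
        per_participant_pct=per_part,
    )
    return df, report


def _validate_trials(trials: pd.DataFrame) -> None:
    required = {"participant_id", "cue", "flanker", "accuracy", "rt_ms"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table is missing columns: {sorted(missing)}")


def _retained(trials: pd.DataFrame) -> pd.DataFrame:
    if "excluded" not in trials.columns:
        trials, _ = flag_exclusions(trials)
    return trials.loc[~trials["excluded"]]


def summarize_conditions(
    trials: pd.DataFrame, exclusion_scope: str = "both"
) -> pd.DataFrame:
    """Per-participant median RT and PE on the cue and flanker margins.

    For every participant the retained test trials are collapsed two ways:
    per cue condition (over flankers) and per flanker condition (over cues),
    plus an overall row. Median RT uses correct retained trials; PE is the
    error proportion over retained trials (``exclusion_scope='rt_only'``
    instead computes PE over all non-practice trials, keeping extreme-RT
    trials in the error count).

    Returns a long frame: participant_id, group, margin, cell, median_rt_ms,
    pe, n_retained, n_correct.
    """
    if exclusion_scope not in ("both", "rt_only"):
        raise ValueError("exclusion_scope must be 'both' or 'rt_only'")
    if "excluded" not in trials.columns:
        trials, _ = flag_exclusions(trials)
    test = trials.loc[trials["exclusion_reason"] != "practice"]
    retained = test.loc[~test["excluded"]]
    pe_base = test if exclusion_scope == "rt_only" else retained

    pieces = []
    for margin, cells in ((CUE_MARGIN, "cue"), (FLANKER_MARGIN, "flanker"), (OVERALL, None)):
        keys = ["participant_id", "group"] + ([cells] if cells else [])
        correct = retained.loc[retained["accuracy"].astype(bool)]
        med = correct.groupby(keys, sort=False, observed=True)["rt_ms"].agg(
            ["median", "size"]
        )
        pe = 1.0 - pe_base.groupby(keys, sort=False, observed=True)["accuracy"].mean()
        n_ret = pe_base.groupby(keys, sort=False, observed=True).size()
        merged = pd.concat(
            {"median_rt_ms": med["median"], "n_correct": med["size"], "pe": pe, "n_retained": n_ret},
            axis=1,
        ).reset_index()
        merged["margin"] = margin
        merged["cell"] = merged[cells] if cells else OVERALL
        pieces.append(
            merged[
                ["participant_id", "group", "margin", "cell", "median_rt_ms", "pe", "n_retained", "n_correct"]
            ]
        )
    out = pd.concat(pieces, ignore_index=True)
    out["n_correct"] = out["n_correct"].fillna(0).astype(int)
    out["n_retained"] = out["n_retained"].fillna(0).astype(int)
    return out


def arcsin_transform(p) -> np.ndarray | float:
    """Variance-stabilising transform of an error proportion: arcsin(sqrt(p))."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out
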