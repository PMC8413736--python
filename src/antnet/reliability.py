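"""Permutation split-half reliability of the network scores.

Each participant's retained test trials are split at random into two
halves; network scores are computed independently on each half; the Pearson
correlation of the half-scores across participants is stepped up to
full-test length with the Spearman–Brown formula 2r/(1+r). Repeating the
split many times (1,000 by default) and averaging the corrected
correlations gives the reliability estimate, with a standard-error-of-the-
mean 95% interval over the permutation values.

By default the split is stratified within every cue x flanker design cell
so both halves contain every condition (an odd cell sends its extra trial
to a random half); an unrestricted within-participant split is available
for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import flag_exclusions
from .scoring import NETWORKS
from .task import CUES, FLANKERS

MEASURES = ("rt", "pe", "composite")

_CUE_IDX = {c: i for i, c in enumerate(CUES)}
_FL_IDX = {f: i for i, f in enumerate(FLANKERS)}

# contrast index pairs on the margins: (margin, hi, lo)
_RT_CONTRASTS = {
    "alerting": ("cue", _CUE_IDX["none"], _CUE_IDX["double"]),
    "orienting": ("cue", _CUE_IDX["central"], _CUE_IDX["spatial"]),
    "executive": ("flanker", _FL_IDX["incongruent"], _FL_IDX["congruent"]),
}


@dataclass(frozen=True)
class ReliabilityEstimate:
    network: str
    measure: str
    n_permutations: int
    mean_corrected_r: float
    ci_low: float
    ci_high: float
    mean_n_dropped: float = 0.0
    per_permutation_values: np.ndarray | None = None


def spearman_brown(r):
    """Step a half-test correlation up to full length: 2r/(1+r)."""
    r = np.asarray(r, dtype=float)
    out = 2.0 * r / (1.0 + r)
    return float(out) if out.ndim == 0 else out


class _SplitEngine:
    """Precomputed arrays for fast repeated half-splits of one trial table."""

    def __init__(self, trials: pd.DataFrame, split: str = "stratified"):
        if split not in ("stratified", "unrestricted"):
            raise ValueError("split must be 'stratified' or 'unrestricted'")
        if "excluded" not in trials.columns:
            trials, _ = flag_exclusions(trials)
        kept = trials.loc[~trials["excluded"]]
        # canonical row order: estimates depend only on the trial set, not
        # on how the table happened to be sorted
        sort_cols = [c for c in ("participant_id", "block", "trial") if c in kept.columns]
        kept = kept.sort_values(sort_cols, kind="stable")
        pids = kept["participant_id"].to_numpy()
        self.participants, pid_codes = np.unique(pids, return_inverse=True)
        self.n_participants = len(self.participants)
        if self.n_participants < 3:
            raise ValueError("need at least 3 participants with retained trials")
        self.pid = pid_codes
        self.cue = kept["cue"].map(_CUE_IDX).to_numpy(dtype=np.int64)
        self.fl = kept["flanker"].map(_FL_IDX).to_numpy(dtype=np.int64)
        self.rt = kept["rt_ms"].to_numpy(dtype=float)
        self.err = 1.0 - kept["accuracy"].to_numpy(dtype=float)
        self.correct = kept["accuracy"].to_numpy(dtype=bool)
        self.n = len(kept)
        cell = self.cue * len(FLANKERS) + self.fl
        self.strata = (
            self.pid * 12 + cell if split == "stratified" else self.pid.copy()
        )
        self.n_strata = int(self.strata.max()) + 1

    def draw_halves(self, rng: np.random.Generator) -> np.ndarray:
        """Random half labels (0/1), balanced within each stratum."""
        order = rng.permutation(self.n)
        gid = self.strata[order]
        sidx = np.argsort(gid, kind="stable")
        sorted_gid = gid[sidx]
        boundaries = np.flatnonzero(np.diff(sorted_gid)) + 1
        starts = np.concatenate(([0], boundaries))
        sizes = np.diff(np.concatenate((starts, [self.n])))
        cumcount = np.arange(self.n) - np.repeat(starts, sizes)
        cc = np.empty(self.n, dtype=np.int64)
        cc[sidx] = cumcount
        offsets = rng.integers(0, 2, self.n_strata)
        half_perm = (cc + offsets[gid]) % 2
        half = np.empty(self.n, dtype=np.int64)
        half[order] = half_perm
        return half

    def _margin_stats(self, codes: np.ndarray, k: int, half: np.ndarray):
        """Median correct RT and PE per participant x margin-cell x half."""
        key = (self.pid * k + codes) * 2 + half
        size = self.n_participants * k * 2

        med = np.full(size, np.nan)
        ckey = key[self.correct]
        grouped = pd.Series(self.rt[self.correct]).groupby(ckey).median()
        med[grouped.index.to_numpy()] = grouped.to_numpy()

        counts = np.bincount(key, minlength=size).astype(float)
        errs = np.bincount(key, weights=self.err, minlength=size)
        with np.errstate(invalid="ignore", divide="ignore"):
            pe = np.where(counts > 0, errs / counts, np.nan)
        shape = (self.n_participants, k, 2)
        return med.reshape(shape), pe.reshape(shape)

    def half_scores(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        """One split: per-network half-scores.

        Returns arrays of shape (n_participants, 2) keyed by
        '<network>_rt' (ms) and '<network>_pe' (percentage points).
        """
        half = self.draw_halves(rng)
        cue_med, cue_pe = self._margin_stats(self.cue, len(CUES), half)
        fl_med, fl_pe = self._margin_stats(self.fl, len(FLANKERS), half)
        out: dict[str, np.ndarray] = {}
        for network, (margin, hi, lo) in _RT_CONTRASTS.items():
            med, pe = (cue_med, cue_pe) if margin == "cue" else (fl_med, fl_pe)
            out[f"{network}_rt"] = med[:, hi, :] - med[:, lo, :]
            out[f"{network}_pe"] = 100.0 * (pe[:, hi, :] - pe[:, lo, :])
        return out


def _composite_halves(scores: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Per-half composites: z over the pooled network stack, averaged over measures."""
    out = {}
    for h in (0, 1):
        rt_stack = np.concatenate([scores[f"{n}_rt"][:, h] for n in NETWORKS])
        pe_stack = np.concatenate([scores[f"{n}_pe"][:, h] for n in NETWORKS])
        rt_m, rt_s = np.nanmean(rt_stack), np.nanstd(rt_stack, ddof=1)
        pe_m, pe_s = np.nanmean(pe_stack), np.nanstd(pe_stack, ddof=1)
        for n in NETWORKS:
            z = (
                (scores[f"{n}_rt"][:, h] - rt_m) / rt_s
                + (scores[f"{n}_pe"][:, h] - pe_m) / pe_s
            ) / 2.0
            out.setdefault(f"{n}_composite", []).append(z)
    return {k: np.column_stack(v) for k, v in out.items()}


def _pairwise_r(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    ok = np.isfinite(a) & np.isfinite(b)
    n_drop = int((~ok).sum())
    if ok.sum() < 3:
        return np.nan, n_drop
    r = np.corrcoef(a[ok], b[ok])[0, 1]
    return float(r), n_drop


def split_half_once(
    trials: pd.DataFrame,
    network: str,
    measure: str,
    rng: np.random.Generator,
    split: str = "stratified",
) -> float:
    """One random split: Spearman–Brown-corrected half-score correlation."""
    engine = _SplitEngine(trials, split=split)
    scores = engine.half_scores(rng)
    if measure == "composite":
        scores.update(_composite_halves(scores))
    arr = scores[f"{network}_{measure}"]
    r, _ = _pairwise_r(arr[:, 0], arr[:, 1])
    return spearman_brown(r)


def split_half_reliability(
    trials: pd.DataFrame,
    network: str,
    measure: str = "rt",
    n_permutations: int = 1000,
    seed: int = 0,
    split: str = "stratified",
    store_values: bool = False,
    ci: str = "sem",
) -> ReliabilityEstimate:
    """Average corrected split-half correlation over random half-splits.

    The 95% interval is mean +/- 1.96 SD/sqrt(n) over the permutation values
    (``ci='percentile'`` gives the empirical 2.5/97.5 percentiles instead).
    Deterministic under a fixed seed.
    """
    table = split_half_reliability_all(
        trials,
        n_permutations=n_permutations,
        seed=seed,
        split=split,
        networks=(network,),
        measures=(measure,),
        store_values=store_values,
        ci=ci,
    )
    return table[0]


def split_half_reliability_all(
    trials: pd.DataFrame,
    n_permutations: int = 1000,
    seed: int = 0,
    split: str = "stratified",
    networks: tuple[str, ...] = NETWORKS,
    measures: tuple[str, ...] = MEASURES,
    store_values: bool = False,
    ci: str = "sem",
) -> list[ReliabilityEstimate]:
    """Reliability of every requested network x measure, sharing the splits.

    Mirrors the study design: each permutation splits all trials once and
    scores every network on the same halves.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    for m in measures:
        if m not in MEASURES:
            raise ValueError(f"unknown measure {m!r}")
    for n in networks:
        if n not in NETWORKS:
            raise ValueError(f"unknown network {n!r}")
    engine = _SplitEngine(trials, split=split)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    need_composite = "composite" in measures

    keys = [(n, m) for n in networks for m in measures]
    values = {k: np.empty(n_permutations) for k in keys}
    dropped = {k: np.empty(n_permutations) for k in keys}
    for i in range(n_permutations):
        scores = engine.half_scores(rng)
        if need_composite:
            scores.update(_composite_halves(scores))
        for n, m in keys:
            arr = scores[f"{n}_{m}"]
            r, n_drop = _pairwise_r(arr[:, 0], arr[:, 1])
            values[(n, m)][i] = spearman_brown(r)
            dropped[(n, m)][i] = n_drop

    out = []
    for n, m in keys:
        vals = values[(n, m)]
        finite = vals[np.isfinite(vals)]
        mean = float(finite.mean())
        if len(finite) >= 2:
            if ci == "percentile":
                lo, hi = np.percentile(finite, [2.5, 97.5])
            else:
                half_width = 1.96 * finite.std(ddof=1) / np.sqrt(len(finite))
                lo, hi = mean - half_width, mean + half_width
        else:
            lo = hi = np.nan
        out.append(
            ReliabilityEstimate(
                network=n,
                measure=m,
                n_permutations=n_permutations,
                mean_corrected_r=mean,
                ci_low=float(lo),
                ci_high=float(hi),
                mean_n_dropped=float(dropped[(n, m)].mean()),
                per_permutation_values=vals if store_values else None,
            )
        )
    return out


def reliability_table(estimates: list[ReliabilityEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "network": [e.network for e in estimates],
            "measure": [e.measure for e in estimates],
            "n_perm": [e.n_permutations for e in estimates],
            "mean_r": [e.mean_corrected_r for e in estimates],
            "ci_low": [e.ci_low for e in estimates],
            "ci_high": [e.ci_high for e in estimates],
            "mean_n_dropped": [e.mean_n_dropped for e in estimates],
        }
    )
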