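"""Synthetic ANT cohorts with realistic reaction-time and error structure.

Each simulated participant is an ex-Gaussian responder: their reaction time
on a trial is a condition-dependent location term (baseline minus alerting
and orienting cue benefits, plus the flanker-conflict cost on incongruent
trials) plus Gaussian noise convolved with an exponential tail — the
standard right-skewed model for RT data. Errors follow a logistic model
with an incongruent-trial penalty; RTs and errors are otherwise independent
given the condition. A small fraction of trials is contaminated by
anticipations (fast guesses under 200 ms) or lapses (no response before
the 1,700 ms deadline), so the exclusion rules downstream have work to do.

Default calibration targets the magnitudes observed in school-age samples
on the child ANT: cohort-level alerting effect near 30 ms, orienting near
43 ms, flanker-conflict cost near 84 ms in the gifted group and about
10 ms larger in the average group, overall error proportions near 2.6% and
4.4% per group, and roughly 0.7% of trials out of range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .task import CUES, FLANKERS, TIMELINE, TrialSpec, schedule_frame

GROUPS: tuple[str, str] = ("gifted", "average")

ANTICIPATION_RANGE_MS = (80.0, 199.0)


@dataclass(frozen=True)
class ResponderParams:
    """Latent generative parameters of one simulated participant.

    RT location shifts are in ms; error parameters are log-odds;
    contamination rates are per-trial probabilities.
    """

    participant_id: str
    group: str
    mu_ms: float = 557.0
    sigma_ms: float = 70.0
    tau_ms: float = 100.0
    alert_benefit_ms: float = 30.0
    orient_benefit_ms: float = 43.0
    flanker_cost_ms: float = 83.7
    error_logit_base: float = -4.48
    error_logit_incong: float = 1.41
    anticipation_rate: float = 0.005
    lapse_rate: float = 0.002

    def __post_init__(self) -> None:
        if self.sigma_ms < 0 or self.tau_ms < 0:
            raise ValueError("sigma_ms and tau_ms must be nonnegative")
        for name in ("anticipation_rate", "lapse_rate"):
            r = getattr(self, name)
            if not 0 <= r < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")


#: between-participant SDs of the responder parameters (same keys as the
#: ResponderParams RT/error fields). Chosen so that observed network-score
#: dispersions and split-half reliabilities land in the empirically typical
#: range for the child ANT: the conflict cost varies a lot across children
#: (hence a reliable executive score) while cue benefits vary little
#: relative to median-estimation noise (hence weakly reliable alerting and
#: especially orienting scores).
DEFAULT_BETWEEN_SDS: dict[str, float] = {
    "mu_ms": 78.0,
    "sigma_ms": 15.0,
    "tau_ms": 25.0,
    "alert_benefit_ms": 14.5,
    "orient_benefit_ms": 6.0,
    "flanker_cost_ms": 25.0,
    "error_logit_base": 0.55,
    "error_logit_incong": 0.30,
}

_POSITIVE_PARAMS = ("sigma_ms", "tau_ms")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level simulation settings (two groups, shared schedule shape)."""

    n_per_group: int = 54
    seed: int = 0
    group_effect_flanker_ms: float = 10.5
    group_effect_error_logit: float = 0.55
    between_participant_sds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BETWEEN_SDS)
    )
    baseline: ResponderParams = ResponderParams("_template", "gifted")
    n_blocks: int = 3
    trials_per_block: int = 96
    n_practice: int = 24
    include_practice: bool = True

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")


def null_config(seed: int = 0, **kwargs) -> CohortConfig:
    """A cohort with no group differences (for type-I-error studies)."""
    return CohortConfig(
        seed=seed, group_effect_flanker_ms=0.0, group_effect_error_logit=0.0, **kwargs
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _simulate_responses(
    p: ResponderParams, frame: pd.DataFrame, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised trial outcomes for one participant over a schedule frame.

    Returns (rt_ms, accuracy); rt is NaN on timeout (lapse or a draw beyond
    the response deadline), and timeouts are scored as errors.
    """
    cue = frame["cue"].to_numpy()
    flanker = frame["flanker"].to_numpy()
    n = len(frame)

    loc = np.full(n, p.mu_ms)
    loc -= p.alert_benefit_ms * (cue != "none")
    loc -= p.orient_benefit_ms * (cue == "spatial")
    loc += p.flanker_cost_ms * (flanker == "incongruent")

    rt = loc + rng.normal(0.0, p.sigma_ms, n) if p.sigma_ms > 0 else loc.copy()
    if p.tau_ms > 0:
        rt = rt + rng.exponential(p.tau_ms, n)

    logit = p.error_logit_base + p.error_logit_incong * (flanker == "incongruent")
    accuracy = rng.random(n) >= _sigmoid(logit)

    contam = rng.random(n)
    anticip = contam < p.anticipation_rate
    lapse = (contam >= p.anticipation_rate) & (
        contam < p.anticipation_rate + p.lapse_rate
    )
    if anticip.any():
        rt[anticip] = rng.uniform(*ANTICIPATION_RANGE_MS, anticip.sum())
    np.maximum(rt, 1.0, out=rt)  # a physical response time cannot be <= 0
    # no response before the deadline: no RT, scored incorrect
    timeout = lapse | (rt > TIMELINE.target_timeout_ms)
    rt[timeout] = np.nan
    accuracy[timeout] = False
    return rt, accuracy


def simulate_trial(
    params: ResponderParams, spec: TrialSpec, rng: np.random.Generator
) -> dict:
    """Simulate a single trial; returns a trial-record dict."""
    frame = pd.DataFrame(
        {"cue": [spec.cue.value], "flanker": [spec.flanker.value]}
    )
    rt, acc = _simulate_responses(params, frame, rng)
    return {
        "participant_id": params.participant_id,
        "group": params.group,
        "block": spec.block_index,
        "trial": spec.trial_index,
        "cue": spec.cue.value,
        "flanker": spec.flanker.value,
        "target_location": spec.target_location,
        "target_direction": spec.target_direction,
        "accuracy": int(acc[0]),
        "rt_ms": float(rt[0]) if np.isfinite(rt[0]) else None,
        "is_practice": spec.is_practice,
    }


def draw_participants(config: CohortConfig, rng: np.random.Generator) -> list[ResponderParams]:
    """Draw per-participant responder parameters from the group models."""
    out: list[ResponderParams] = []
    sds = config.between_participant_sds
    for group in GROUPS:
        base = replace(config.baseline, participant_id="_", group=group)
        if group == "average":
            base = replace(
                base,
                flanker_cost_ms=base.flanker_cost_ms + config.group_effect_flanker_ms,
                error_logit_base=base.error_logit_base + config.group_effect_error_logit,
            )
        for i in range(config.n_per_group):
            pid = f"{group[:3]}{i + 1:03d}"
            draws = {}
            for name, sd in sds.items():
                val = getattr(base, name) + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                if name in _POSITIVE_PARAMS:
                    # truncate at a small floor, but never inflate a
                    # deliberately noiseless baseline
                    val = max(val, min(5.0, getattr(base, name)))
                draws[name] = val
            out.append(replace(base, participant_id=pid, **draws))
    return out


def simulate_cohort(
    config: CohortConfig | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Simulate a full two-group cohort; returns the long trial table.

    Every participant gets an independent, balanced, freshly randomised
    schedule. All randomness descends from ``config.seed`` (overridable via
    ``seed``) through named child streams, so schedules, participant draws
    and responses are reproducible independently.
    """
    config = config or CohortConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    root = np.random.SeedSequence(config.seed)
    params_ss, sched_ss, resp_ss = root.spawn(3)
    participants = draw_participants(config, np.random.default_rng(params_ss))

    sched_children = sched_ss.spawn(len(participants))
    resp_children = resp_ss.spawn(len(participants))

    tables: list[pd.DataFrame] = []
    for p, s_ss, r_ss in zip(participants, sched_children, resp_children):
        frame = schedule_frame(
            np.random.default_rng(s_ss),
            n_blocks=config.n_blocks,
            trials_per_block=config.trials_per_block,
            n_practice=config.n_practice if config.include_practice else 0,
        )
        rt, acc = _simulate_responses(p, frame, np.random.default_rng(r_ss))
        frame = frame.copy()
        frame.insert(0, "participant_id", p.participant_id)
        frame.insert(1, "group", p.group)
        frame["accuracy"] = acc.astype(int)
        frame["rt_ms"] = rt
        tables.append(frame)
    out = pd.concat(tables, ignore_index=True)
    return out.drop(columns=["fixation_ms"])
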