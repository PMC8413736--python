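"""Monte-Carlo experiments over synthetic cohorts.

Used to check that the pipeline recovers planted group effects (sign
recovery of the executive-control difference) and that the group x network
interaction test holds its nominal size under a null cohort. Replicates are
independent: each gets its own seed drawn from one root sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import CohortConfig, null_config, simulate_cohort
from .inference import mixed_anova, recommended_p
from .scoring import score_trials


@dataclass(frozen=True)
class ReplicateOutcome:
    seed: int
    executive_diff: float  # mean composite, average - gifted
    p_group: float
    p_interaction: float
    executive_rt_gifted: float
    alerting_rt: float
    orienting_rt: float
    executive_rt: float
    pe_overall_gifted: float
    pe_overall_average: float


def run_replicate(config: CohortConfig, seed: int) -> ReplicateOutcome:
    """Simulate one cohort, score it, and run the mixed ANOVA."""
    trials = simulate_cohort(replace(config, seed=seed))
    scores = score_trials(trials)
    result = mixed_anova(scores)

    exe = scores.loc[scores["network"] == "executive"]
    diff = (
        exe.loc[exe["group"] == "average", "composite"].mean()
        - exe.loc[exe["group"] == "gifted", "composite"].mean()
    )
    rt_means = scores.groupby("network")["rt_diff_ms"].mean()
    exe_rt_gifted = exe.loc[exe["group"] == "gifted", "rt_diff_ms"].mean()

    test = trials.loc[~trials["is_practice"]]
    rt = test["rt_ms"]
    kept = test.loc[rt.notna() & (rt >= 200) & (rt <= 1700)]
    pe = 100.0 * (1.0 - kept.groupby("group")["accuracy"].mean())

    return ReplicateOutcome(
        seed=seed,
        executive_diff=float(diff),
        p_group=recommended_p(result, "group"),
        p_interaction=recommended_p(result, "group:network"),
        executive_rt_gifted=float(exe_rt_gifted),
        alerting_rt=float(rt_means["alerting"]),
        orienting_rt=float(rt_means["orienting"]),
        executive_rt=float(rt_means["executive"]),
        pe_overall_gifted=float(pe["gifted"]),
        pe_overall_average=float(pe["average"]),
    )


def _replicate_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def sign_recovery(
    n_replicates: int = 200, seed: int = 0, config: CohortConfig | None = None
) -> pd.DataFrame:
    """Planted-effect replicates; one row per cohort."""
    config = config or CohortConfig()
    rows = [run_replicate(config, s) for s in _replicate_seeds(seed, n_replicates)]
    return pd.DataFrame([r.__dict__ for r in rows])


def type_i_error(
    n_replicates: int = 500, seed: int = 1, alpha: float = 0.05
) -> pd.DataFrame:
    """Null-cohort replicates (no group effects); one row per cohort."""
    rows = [
        run_replicate(null_config(), s) for s in _replicate_seeds(seed, n_replicates)
    ]
    return pd.DataFrame([r.__dict__ for r in rows])
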