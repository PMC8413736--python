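import numpy as np
import pandas as pd
import pytest

from antnet.cohort import CohortConfig, simulate_cohort
from antnet.preprocessing import flag_exclusions
from antnet.scoring import score_trials

SMALL = dict(n_per_group=10, n_blocks=2, trials_per_block=48, n_practice=12)


@pytest.fixture(scope="session")
def small_trials() -> pd.DataFrame:
    """A small but structurally complete synthetic cohort (20 participants)."""
    return simulate_cohort(CohortConfig(seed=321, **SMALL))


@pytest.fixture(scope="session")
def cohort_trials() -> pd.DataFrame:
    """A full-size cohort (54 per group, 288 test trials each)."""
    return simulate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def cohort_flagged(cohort_trials):
    flagged, report = flag_exclusions(cohort_trials)
    return flagged, report


@pytest.fixture(scope="session")
def cohort_scores(cohort_flagged) -> pd.DataFrame:
    flagged, _ = cohort_flagged
    return score_trials(flagged)


def toy_mixed_data(seed: int = 42, n_per: int = 8) -> pd.DataFrame:
    """Deterministic 2-group x 3-network long table for ANOVA oracles.

    The seed-42, n=8 instance was also scored with an independent
    multivariate least-squares oracle in R (car::Anova, sum contrasts);
    those frozen values live in the tests that use it.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g, lab in enumerate(["a", "b"]):
        base = (
            rng.normal(0, 1, (n_per, 1))
            + rng.normal(0, [0.5, 1.0, 2.0], (n_per, 3))
            + np.array([[0.0, 0.5, 1.0]])
            + g * np.array([[0.0, 0.2, 0.8]])
        )
        for i in range(n_per):
            for j, net in enumerate(["alerting", "orienting", "executive"]):
                rows.append((f"{lab}{i}", lab, net, base[i, j]))
    return pd.DataFrame(
        rows, columns=["participant_id", "group", "network", "composite"]
    )
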