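"""Design of the child Attention Network Test (ANT).

The ANT is a cued flanker task: each trial shows one of four warning cues
(none, central, double, spatial) followed, after a fixed stimulus-onset
asynchrony, by a target fish that is alone (neutral) or flanked by fish
swimming the same (congruent) or opposite (incongruent) direction. The
module encodes the condition taxonomy, the trial timeline constants, and
balanced, seeded trial-schedule generation. Everything downstream (the
simulator, the preprocessing, the scoring) speaks in these terms.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class CueCondition(str, enum.Enum):
    """Warning-cue condition preceding the target."""

    NONE = "none"
    CENTRAL = "central"
    DOUBLE = "double"
    SPATIAL = "spatial"


class FlankerCondition(str, enum.Enum):
    """Flanker (target surround) condition."""

    NEUTRAL = "neutral"
    CONGRUENT = "congruent"
    INCONGRUENT = "incongruent"


CUES: tuple[str, ...] = tuple(c.value for c in CueCondition)
FLANKERS: tuple[str, ...] = tuple(f.value for f in FlankerCondition)
TARGET_LOCATIONS: tuple[str, ...] = ("above", "below")
TARGET_DIRECTIONS: tuple[str, ...] = ("left", "right")

#: cue x flanker x location x direction fully crossed
N_DESIGN_CELLS = len(CUES) * len(FLANKERS) * len(TARGET_LOCATIONS) * len(TARGET_DIRECTIONS)

FIXATION_RANGE_MS = (400, 1400)


@dataclass(frozen=True)
class TimelineConstants:
    """Fixed trial-timeline durations of the child ANT."""

    cue_duration_ms: int = 100
    soa_ms: int = 400
    target_timeout_ms: int = 1700
    practice_feedback_ms: int = 500
    interblock_break_s: int = 5

    def __post_init__(self) -> None:
        for name in (
            "cue_duration_ms",
            "soa_ms",
            "target_timeout_ms",
            "practice_feedback_ms",
            "interblock_break_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


TIMELINE = TimelineConstants()


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial (design cell + jittered fixation)."""

    block_index: int
    trial_index: int
    cue: CueCondition
    flanker: FlankerCondition
    target_location: str
    target_direction: str
    fixation_ms: int
    is_practice: bool = False

    def __post_init__(self) -> None:
        lo, hi = FIXATION_RANGE_MS
        if not lo <= self.fixation_ms <= hi:
            raise ValueError(f"fixation_ms must lie in [{lo}, {hi}]")
        if not self.is_practice and self.block_index < 1:
            raise ValueError("test trials require block_index >= 1")
        if self.trial_index < 1:
            raise ValueError("trial_index must be >= 1")


def schedule_frame(
    rng: np.random.Generator,
    n_blocks: int = 3,
    trials_per_block: int = 96,
    n_practice: int = 24,
) -> pd.DataFrame:
    """Vectorised schedule generator; columns mirror the trial CSV dialect.

    Practice trials carry ``block = 0``; test blocks are 1..n_blocks with
    every cue x flanker x location x direction cell appearing equally often
    within each block, in seeded random order.
    """
    if trials_per_block % N_DESIGN_CELLS != 0:
        raise ValueError(
            f"trials_per_block must be divisible by {N_DESIGN_CELLS} "
            "(4 cues x 3 flankers x 2 locations x 2 directions)"
        )
    cells = np.arange(N_DESIGN_CELLS)
    reps = trials_per_block // N_DESIGN_CELLS

    blocks: list[np.ndarray] = []
    block_ids: list[np.ndarray] = []
    practice_flags: list[np.ndarray] = []

    if n_practice > 0:
        # practice is not required to balance; draw from a shuffled tiling so
        # short practice blocks still spread over the design
        pool = np.tile(cells, int(np.ceil(n_practice / N_DESIGN_CELLS)))
        pool = rng.permutation(pool)[:n_practice]
        blocks.append(pool)
        block_ids.append(np.zeros(n_practice, dtype=int))
        practice_flags.append(np.ones(n_practice, dtype=bool))

    for b in range(1, n_blocks + 1):
        order = rng.permutation(np.tile(cells, reps))
        blocks.append(order)
        block_ids.append(np.full(trials_per_block, b, dtype=int))
        practice_flags.append(np.zeros(trials_per_block, dtype=bool))

    cell = np.concatenate(blocks)
    block = np.concatenate(block_ids)
    practice = np.concatenate(practice_flags)
    n = cell.size

    # decode the flat cell index
    cue_i, rem = np.divmod(cell, len(FLANKERS) * 4)
    fl_i, rem = np.divmod(rem, 4)
    loc_i, dir_i = np.divmod(rem, 2)

    lo, hi = FIXATION_RANGE_MS
    fixation = np.rint(rng.uniform(lo, hi, size=n)).astype(int)

    trial = np.concatenate([np.arange(1, g.size + 1) for g in blocks])
    return pd.DataFrame(
        {
            "block": block,
            "trial": trial,
            "cue": np.asarray(CUES, dtype=object)[cue_i],
            "flanker": np.asarray(FLANKERS, dtype=object)[fl_i],
            "target_location": np.asarray(TARGET_LOCATIONS, dtype=object)[loc_i],
            "target_direction": np.asarray(TARGET_DIRECTIONS, dtype=object)[dir_i],
            "fixation_ms": fixation,
            "is_practice": practice,
        }
    )


def generate_schedule(
    seed: int | np.random.Generator,
    n_blocks: int = 3,
    trials_per_block: int = 96,
    n_practice: int = 24,
) -> list[TrialSpec]:
    """Generate a full session schedule: practice first, then balanced blocks."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frame = schedule_frame(rng, n_blocks, trials_per_block, n_practice)
    return [
        TrialSpec(
            block_index=int(row.block),
            trial_index=int(row.trial),
            cue=CueCondition(row.cue),
            flanker=FlankerCondition(row.flanker),
            target_location=row.target_location,
            target_direction=row.target_direction,
            fixation_ms=int(row.fixation_ms),
            is_practice=bool(row.is_practice),
        )
        for row in frame.itertuples(index=False)
    ]


def schedule_to_csv(schedule: list[TrialSpec], path) -> None:
    pd.DataFrame(
        {
            "block": [t.block_index for t in schedule],
            "trial": [t.trial_index for t in schedule],
            "cue": [t.cue.value for t in schedule],
            "flanker": [t.flanker.value for t in schedule],
            "target_location": [t.target_location for t in schedule],
            "target_direction": [t.target_direction for t in schedule],
            "fixation_ms": [t.fixation_ms for t in schedule],
            "is_practice": [int(t.is_practice) for t in schedule],
        }
    ).to_csv(path, index=False)


def schedule_from_csv(path) -> list[TrialSpec]:
    frame = pd.read_csv(path)
    return [
        TrialSpec(
            block_index=int(row.block),
            trial_index=int(row.trial),
            cue=CueCondition(row.cue),
            flanker=FlankerCondition(row.flanker),
            target_location=row.target_location,
            target_direction=row.target_direction,
            fixation_ms=int(row.fixation_ms),
            is_practice=bool(row.is_practice),
        )
        for row in frame.itertuples(index=False)
    ]
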