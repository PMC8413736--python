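"""Trial-table file format: a declared CSV dialect with strict validation.

No standard interchange format exists for trial-level behavioral data, so
the trial table is a plain CSV whose dialect (delimiter, column names,
missing-value token) is fully declared and remappable — external deposits
with different column headings are absorbed by the mapping rather than by
editing files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task import CUES, FLANKERS

REQUIRED_COLUMNS = (
    "participant_id",
    "group",
    "block",
    "trial",
    "cue",
    "flanker",
    "target_location",
    "target_direction",
    "accuracy",
    "rt_ms",
)


@dataclass(frozen=True)
class TrialTableDialect:
    delimiter: str = ","
    missing_token: str = ""
    encoding: str = "utf-8"
    #: external-name -> canonical-name remapping applied after read
    column_map: dict[str, str] = field(default_factory=dict)


class TrialValidationError(ValueError):
    """Raised with row-addressed messages when a trial table is malformed."""


def read_trials(path, dialect: TrialTableDialect | None = None) -> pd.DataFrame:
    """Read and validate a trial CSV; returns the canonical long table."""
    dialect = dialect or TrialTableDialect()
    df = pd.read_csv(
        path,
        sep=dialect.delimiter,
        encoding=dialect.encoding,
        na_values=[dialect.missing_token],
        keep_default_na=True,
    )
    if dialect.column_map:
        df = df.rename(columns=dialect.column_map)
    return validate_trials(df)


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrialValidationError(f"missing columns: {missing}")
    problems: list[str] = []

    for col, vocab in (("cue", CUES), ("flanker", FLANKERS)):
        bad = ~df[col].isin(vocab)
        for row in df.index[bad][:10]:
            problems.append(f"row {row}: invalid {col} label {df.at[row, col]!r}")

    acc = pd.to_numeric(df["accuracy"], errors="coerce")
    bad_acc = ~acc.isin([0, 1])
    for row in df.index[bad_acc][:10]:
        problems.append(f"row {row}: accuracy must be 0 or 1, got {df.at[row, 'accuracy']!r}")

    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    bad_rt = rt.notna() & (rt < 0)
    for row in df.index[bad_rt][:10]:
        problems.append(f"row {row}: negative rt_ms {df.at[row, 'rt_ms']!r}")
    unparsed = df["rt_ms"].notna() & rt.isna()
    for row in df.index[unparsed][:10]:
        problems.append(f"row {row}: non-numeric rt_ms {df.at[row, 'rt_ms']!r}")

    dupes = df.duplicated(subset=["participant_id", "block", "trial"], keep=False)
    if "is_practice" in df.columns:
        dupes &= ~df["is_practice"].astype(bool)
    if dupes.any():
        first = df.index[dupes][0]
        problems.append(
            f"row {first}: duplicate (participant, block, trial) key "
            f"{tuple(df.loc[first, ['participant_id', 'block', 'trial']])}"
        )

    if problems:
        raise TrialValidationError("; ".join(problems))

    out = df.copy()
    out["accuracy"] = acc.astype(int)
    out["rt_ms"] = rt
    if "is_practice" not in out.columns:
        out["is_practice"] = out["block"] == 0
    out["is_practice"] = out["is_practice"].astype(bool)
    return out


def write_trials(df: pd.DataFrame, path, dialect: TrialTableDialect | None = None) -> None:
    dialect = dialect or TrialTableDialect()
    cols = [c for c in REQUIRED_COLUMNS if c in df.columns]
    extra = [c for c in ("is_practice",) if c in df.columns]
    out = df[cols + extra].copy()
    if "is_practice" in out.columns:
        out["is_practice"] = out["is_practice"].astype(int)
    out.to_csv(
        path,
        sep=dialect.delimiter,
        index=False,
        na_rep=dialect.missing_token,
        encoding=dialect.encoding,
        float_format="%.6g",
    )
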