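"""CSV input/output for cohort and diary tables.

Dialect: comma-separated UTF-8 with a header row; an empty field is a
missing value.  Cohort columns: student_id, gender, age, weight_kg, audit,
motivation, arm, addon_arm[, true_class].  Diary columns (long format):
student_id, wave, weekday, drinks, hours.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ADDON_ARMS, ARMS, DAYS_PER_WEEK, N_WAVES

__all__ = ["read_cohort", "read_diaries", "write_cohort", "write_diaries"]

COHORT_COLUMNS = ["student_id", "gender", "age", "weight_kg", "audit",
                  "motivation", "arm", "addon_arm"]
DIARY_COLUMNS = ["student_id", "wave", "weekday", "drinks", "hours"]


class MalformedInputError(ValueError):
    """Raised on malformed cohort/diary files; message lists offending rows."""


def _offenders(df: pd.DataFrame, bad_mask, what: str) -> None:
    bad = np.flatnonzero(np.asarray(bad_mask))
    if bad.size:
        lines = ", ".join(str(i + 2) for i in bad[:20])   # +2: header + 1-based
        more = "" if bad.size <= 20 else f" (+{bad.size - 20} more)"
        raise MalformedInputError(f"{what} at file line(s) {lines}{more}")


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV."""
    df = pd.read_csv(path, dtype={"student_id": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedInputError(f"cohort file missing columns {missing}")
    _offenders(df, ~df["gender"].isin(["M", "W"]), "unknown gender code")
    _offenders(df, ~df["arm"].isin(ARMS), "unknown arm")
    _offenders(df, ~df["addon_arm"].isin(ADDON_ARMS), "unknown addon arm")
    _offenders(df, df["student_id"].duplicated(), "duplicate student_id")
    _offenders(df, (df["audit"] < 0) | (df["audit"] > 40), "AUDIT outside 0-40")
    _offenders(df, (df["motivation"] < 0) | (df["motivation"] > 10),
               "motivation outside 0-10")
    _offenders(df, df["weight_kg"] <= 0, "nonpositive weight")
    return df


def read_diaries(path) -> pd.DataFrame:
    """Read and validate a long-format diary CSV."""
    df = pd.read_csv(path, dtype={"student_id": str})
    missing = [c for c in DIARY_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedInputError(f"diary file missing columns {missing}")
    if df.empty:
        raise MalformedInputError("no observations: diary file is empty")
    _offenders(df, ~df["wave"].isin(range(N_WAVES)), "wave outside 0-3")
    _offenders(df, ~df["weekday"].isin(range(DAYS_PER_WEEK)),
               "weekday outside 0-6")
    _offenders(df, df["drinks"] < 0, "negative drinks")
    _offenders(df, df["hours"] <= 0, "nonpositive hours")
    _offenders(df, df.duplicated(["student_id", "wave", "weekday"]),
               "duplicate (student, wave, weekday)")
    return df


def write_cohort(students: pd.DataFrame, path) -> None:
    students.to_csv(path, index=False)


def write_diaries(diaries: pd.DataFrame, path) -> None:
    diaries.to_csv(path, index=False)
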