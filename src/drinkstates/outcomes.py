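"""Weekly drinking outcomes derived from diary weeks and AUDIT scores.

The five primary drinking parameters per student and wave are quantity
(standard drinks/week), frequency (drinking occasions/week), binge
occasions/week, weekly mean eBAC and peak eBAC over the recall window;
plus the hazardous (AUDIT >= 6 women / >= 8 men) and excessive (> 9 / > 14
drinks per week, Swedish national recommendation) classifications.

A diary day with at least one drink counts as one occasion; a binge
occasion is a day at or above the gendered heavy-episodic threshold
(>= 4 drinks women / >= 5 men by default).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .ebac import DEFAULT_CONSTANTS, WidmarkConstants, peak_ebac_month, weekly_mean_ebac

__all__ = ["weekly_quantity", "weekly_frequency", "binge_occasions",
           "is_hazardous", "is_excessive", "outcomes_table",
           "BINGE_THRESHOLD", "HAZARDOUS_AUDIT", "EXCESSIVE_WEEKLY"]

BINGE_THRESHOLD = {"W": 4, "M": 5}       # drinks per occasion
HAZARDOUS_AUDIT = {"W": 6, "M": 8}       # AUDIT points, inclusive
EXCESSIVE_WEEKLY = {"W": 9, "M": 14}     # drinks per week, exclusive


def _week(drinks_week) -> np.ndarray:
    w = np.asarray(drinks_week, dtype=float)
    if w.shape != (7,):
        raise ValueError("a diary week has 7 daily drink counts")
    return w


def weekly_quantity(drinks_week) -> float:
    """Total standard drinks over the week; NaN if the week is unobserved."""
    w = _week(drinks_week)
    if np.all(np.isnan(w)):
        return float("nan")
    return float(np.nansum(w))


def weekly_frequency(drinks_week) -> float:
    """Number of drinking occasions (days with >= 1 drink); NaN if unobserved."""
    w = _week(drinks_week)
    if np.all(np.isnan(w)):
        return float("nan")
    return float(np.nansum(w >= 1))


def binge_occasions(drinks_week, gender: str,
                    thresholds: dict = BINGE_THRESHOLD) -> float:
    """Days at or above the gendered heavy-episodic threshold; NaN if unobserved."""
    w = _week(drinks_week)
    if np.all(np.isnan(w)):
        return float("nan")
    return float(np.nansum(w >= thresholds[gender]))


def is_hazardous(audit: float, gender: str,
                 thresholds: dict = HAZARDOUS_AUDIT) -> bool:
    """Hazardous use screen: AUDIT >= 6 (women) / >= 8 (men)."""
    if not 0 <= audit <= 40:
        raise ValueError(f"AUDIT score {audit} outside 0-40")
    return bool(audit >= thresholds[gender])


def is_excessive(quantity: float, gender: str,
                 limits: dict = EXCESSIVE_WEEKLY) -> bool:
    """Excessive weekly drinking: strictly above 9 (women) / 14 (men) drinks."""
    if quantity < 0:
        raise ValueError("weekly quantity must be nonnegative")
    return bool(quantity > limits[gender])


def outcomes_table(students: pd.DataFrame, diaries: pd.DataFrame,
                   constants: WidmarkConstants = DEFAULT_CONSTANTS,
                   binge_thresholds: dict = BINGE_THRESHOLD) -> pd.DataFrame:
    """Per student-and-wave outcome table.

    Columns: quantity, frequency, binge_occasions, weekly_mean_ebac,
    peak_ebac_month, excessive.  The peak-eBAC recall window is the wave's
    own diary week (the diary observes one week per wave).  Unobserved
    waves yield NaN outcomes and a missing ``excessive`` flag.
    """
    info = students.set_index("student_id")
    rows = []
    for (sid, wave), grp in diaries.groupby(["student_id", "wave"], sort=True):
        grp = grp.sort_values("weekday")
        drinks = grp["drinks"].to_numpy(dtype=float)
        hours = grp["hours"].to_numpy(dtype=float)
        gender = info.at[sid, "gender"]
        weight = float(info.at[sid, "weight_kg"])
        q = weekly_quantity(drinks)
        rows.append({
            "student_id": sid,
            "wave": int(wave),
            "quantity": q,
            "frequency": weekly_frequency(drinks),
            "binge_occasions": binge_occasions(drinks, gender, binge_thresholds),
            "weekly_mean_ebac": weekly_mean_ebac(drinks, hours, gender, weight,
                                                 constants),
            "peak_ebac_month": peak_ebac_month(drinks, hours, gender, weight,
                                               constants),
            "excessive": (math.nan if math.isnan(q)
                          else is_excessive(q, gender)),
        })
    return pd.DataFrame(rows)
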