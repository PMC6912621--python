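"""Estimated blood alcohol concentration (eBAC) via the Widmark formula.

A single occasion's eBAC is

    eBAC = 100 * (drinks * grams_per_drink) / (weight_g * r)  -  beta * hours

on the percent (g/dL) scale, floored at zero; ``r`` is the gendered body
water distribution ratio and ``beta`` the elimination rate.  Defaults use
the conventional Widmark constants (r = 0.68 men / 0.55 women,
beta = 0.017 %/h) and the Swedish 12 g standard drink.  Outputs can be
reported in percent or per-mille (g/L, 10x percent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = ["WidmarkConstants", "ebac_occasion", "weekly_mean_ebac",
           "peak_ebac_month"]


@dataclass(frozen=True)
class WidmarkConstants:
    r_by_gender: Mapping[str, float] = field(
        default_factory=lambda: {"M": 0.68, "W": 0.55})
    beta: float = 0.017                  # elimination, percent per hour
    grams_per_standard_drink: float = 12.0
    output_scale: str = "percent_g_per_dL"

    def __post_init__(self):
        if self.beta <= 0 or self.grams_per_standard_drink <= 0:
            raise ValueError("beta and grams_per_standard_drink must be positive")
        for g, r in self.r_by_gender.items():
            if not 0 < r <= 1:
                raise ValueError(f"r for gender {g!r} must lie in (0, 1]")
        if self.output_scale not in ("percent_g_per_dL", "permille_g_per_L"):
            raise ValueError(f"unknown output_scale {self.output_scale!r}")

    @property
    def scale_factor(self) -> float:
        return 10.0 if self.output_scale == "permille_g_per_L" else 1.0


DEFAULT_CONSTANTS = WidmarkConstants()


def ebac_occasion(drinks, hours, gender: str, weight: float,
                  constants: WidmarkConstants = DEFAULT_CONSTANTS):
    """eBAC after one drinking occasion, on the configured output scale.

    ``drinks`` may be a scalar or array; elimination over ``hours`` is
    subtracted and the result floored at zero.  Zero drinks give exactly 0.
    """
    drinks = np.asarray(drinks, dtype=float)
    hours = np.asarray(hours, dtype=float)
    if np.any(weight <= 0) or np.any(hours[~np.isnan(hours)] <= 0):
        raise ValueError("weight and hours must be positive")
    if np.any(drinks[~np.isnan(drinks)] < 0):
        raise ValueError("drinks must be nonnegative")
    r = constants.r_by_gender[gender]
    grams = drinks * constants.grams_per_standard_drink
    percent = 100.0 * grams / (weight * 1000.0 * r) - constants.beta * hours
    out = np.maximum(0.0, percent) * constants.scale_factor
    out = np.where(drinks == 0, 0.0, out)
    return float(out) if out.ndim == 0 else out


def weekly_mean_ebac(drinks_week, hours_week, gender: str, weight: float,
                     constants: WidmarkConstants = DEFAULT_CONSTANTS) -> float:
    """Mean occasion eBAC over a diary week, non-drinking days counting as 0.

    A fully missing week yields NaN, never 0.
    """
    drinks = np.asarray(drinks_week, dtype=float)
    hours = np.asarray(hours_week, dtype=float)
    if drinks.shape != (7,):
        raise ValueError("a diary week has 7 daily drink counts")
    if np.all(np.isnan(drinks)):
        return float("nan")
    vals = np.zeros(7)
    for i in range(7):
        if np.isnan(drinks[i]) or drinks[i] == 0:
            continue
        h = hours[i] if np.isfinite(hours[i]) else max(1.0, drinks[i] / 2.0)
        vals[i] = ebac_occasion(drinks[i], h, gender, weight, constants)
    return float(vals.sum() / 7.0)


def peak_ebac_month(drinks_days, hours_days, gender: str, weight: float,
                    constants: WidmarkConstants = DEFAULT_CONSTANTS) -> float:
    """Maximum single-occasion eBAC over all observed days in a recall window.

    NaN if the window contains no observed day.
    """
    drinks = np.asarray(drinks_days, dtype=float).ravel()
    hours = np.asarray(hours_days, dtype=float).ravel()
    observed = ~np.isnan(drinks)
    if not observed.any():
        return float("nan")
    peak = 0.0
    for d, h in zip(drinks[observed], hours[observed]):
        if d == 0:
            continue
        if not np.isfinite(h):
            h = max(1.0, d / 2.0)
        peak = max(peak, ebac_occasion(d, h, gender, weight, constants))
    return float(peak)
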