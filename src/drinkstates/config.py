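"""Configuration objects for the synthetic cohort generator.

The generator emulates a three-arm smartphone-app trial in university
students: a large cohort randomized 1:1:1 (two eBAC-feedback apps vs.
assessment-only control), weekly drinking diaries at four waves (baseline,
7, 14 and 20 weeks), a nested add-on randomization for excessive drinkers,
and questionnaire-level nonresponse at follow-up waves.

Latent structure: each student belongs to one drinking class.  Seven
"weekday" classes drink predominantly on one specific weekday (weekend
classes are the most prevalent and the heaviest, as is typical for Swedish
student drinking), and a small "frequent-heavy" class (~7% of the cohort)
drinks most days of the week.  Day to day, a student's behaviour follows the
pattern of a class; with probability ``state_persistence`` they keep their
current pattern, otherwise they switch lastingly to a uniformly random
other class.  Occasional switches are what produce both continual and
itinerant members of the frequent-heavy pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

WEEKDAYS = ("monday", "tuesday", "wednesday", "thursday",
            "friday", "saturday", "sunday")
ARMS = ("control", "promillekoll", "partyplanner")
ADDON_ARMS = ("none", "telecoach", "waitlist", "assessment_control")
N_WAVES = 4
DAYS_PER_WEEK = 7
SEQ_LEN = N_WAVES * DAYS_PER_WEEK  # 28 daily observations per student


class ConfigurationError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


@dataclass
class LatentClassSpec:
    """One latent drinking class.

    Parameters
    ----------
    label : str
        Class name (e.g. ``"friday"`` or ``"frequent_heavy"``).
    prevalence : float
        Population share of the class; prevalences must sum to 1.
    drink_prob_by_weekday : sequence of 7 floats
        Probability of any drinking on each weekday (Monday first), before
        arm-by-wave log-odds shifts.
    quantity_mean_given_drinking : float
        Mean standard drinks on a drinking day (> 1; the mean of the
        zero-truncated Poisson used for quantities).
    quantity_dispersion : float, optional
        Reserved for overdispersed quantity families; the default
        zero-truncated Poisson has no free dispersion, so the value is
        validated (must be positive if given) but unused.
    state_persistence : float
        Daily probability of keeping the current behavioural pattern.
    frequent_heavy : bool
        Marks the (single) frequent-heavy class.
    age_shift, audit_shift, motivation_shift, male_logodds_shift : float
        Additive covariate shifts for members of this class, used to give
        the frequent-heavy class its distinct baseline profile.
    """

    label: str
    prevalence: float
    drink_prob_by_weekday: Sequence[float]
    quantity_mean_given_drinking: float
    quantity_dispersion: float | None = None
    state_persistence: float = 0.99
    frequent_heavy: bool = False
    age_shift: float = 0.0
    audit_shift: float = 0.0
    motivation_shift: float = 0.0
    male_logodds_shift: float = 0.0

    def __post_init__(self) -> None:
        probs = np.asarray(self.drink_prob_by_weekday, dtype=float)
        if probs.shape != (DAYS_PER_WEEK,):
            raise ConfigurationError(
                f"class {self.label!r}: drink_prob_by_weekday must have "
                f"{DAYS_PER_WEEK} entries, got shape {probs.shape}")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ConfigurationError(
                f"class {self.label!r}: drink probabilities must lie in [0, 1]")
        self.drink_prob_by_weekday = tuple(float(p) for p in probs)
        if not 0.0 <= self.prevalence <= 1.0:
            raise ConfigurationError(
                f"class {self.label!r}: prevalence {self.prevalence} not in [0, 1]")
        if self.quantity_mean_given_drinking <= 0:
            raise ConfigurationError(
                f"class {self.label!r}: quantity mean must be positive")
        if self.quantity_dispersion is not None and self.quantity_dispersion <= 0:
            raise ConfigurationError(
                f"class {self.label!r}: quantity dispersion must be positive")
        if not 0.0 <= self.state_persistence <= 1.0:
            raise ConfigurationError(
                f"class {self.label!r}: state_persistence not in [0, 1]")


def _weekday_class(idx: int, own_day_prob: float, off_day_prob: float,
                   prevalence: float, quantity_mean: float) -> LatentClassSpec:
    probs = [off_day_prob] * DAYS_PER_WEEK
    probs[idx] = own_day_prob
    return LatentClassSpec(
        label=WEEKDAYS[idx],
        prevalence=prevalence,
        drink_prob_by_weekday=probs,
        quantity_mean_given_drinking=quantity_mean,
        state_persistence=0.99,
    )


def default_class_spec() -> list[LatentClassSpec]:
    """Default latent classes: seven weekday classes plus frequent-heavy.

    Weekday prevalences and quantities are weekend-weighted (Friday and
    Saturday drinkers are the most common and the heaviest).  The
    frequent-heavy class drinks on 65% of days (4.55 expected drinking
    days/week), at roughly 3.6 drinks per occasion, with a very sticky
    pattern and older, more male, higher-AUDIT members.
    """
    prevalences = (0.03, 0.05, 0.08, 0.12, 0.28, 0.23, 0.14)
    quantities = (2.2, 2.8, 3.3, 3.9, 5.2, 5.8, 2.5)
    classes = [
        _weekday_class(i, own_day_prob=0.85, off_day_prob=0.06,
                       prevalence=prevalences[i], quantity_mean=quantities[i])
        for i in range(DAYS_PER_WEEK)
    ]
    classes.append(LatentClassSpec(
        label="frequent_heavy",
        prevalence=0.07,
        drink_prob_by_weekday=(0.65,) * DAYS_PER_WEEK,
        quantity_mean_given_drinking=3.6,
        state_persistence=0.995,
        frequent_heavy=True,
        age_shift=3.9,
        audit_shift=3.0,
        motivation_shift=0.8,
        male_logodds_shift=0.88,
    ))
    return classes


@dataclass
class SimConfig:
    """Full configuration of a synthetic cohort.

    Defaults mirror the emulated trial: n=2166 students randomized 1:1:1,
    two-thirds women, hazardous-range AUDIT scores, follow-up response
    rates in the 55-83% band, and a mild downward drift in daily drinking
    probability that is strongest in the app arms (control declines least;
    the control-vs-promillekoll gap is ~0.03 log-odds/wave, i.e. a trend
    odds ratio of ~1.03).
    """

    n_students: int = 2166
    arm_ratio: tuple[float, float, float] = (1.0, 1.0, 1.0)
    prop_women: float = 0.675
    age_mean: float = 25.6
    age_sd: float = 6.2
    weight_mean_by_gender: Mapping[str, float] = field(
        default_factory=lambda: {"W": 70.0, "M": 82.0})
    weight_sd_by_gender: Mapping[str, float] = field(
        default_factory=lambda: {"W": 10.0, "M": 12.0})
    audit_mean: float = 10.8
    audit_sd: float = 4.1
    motivation_mean: float = 4.0
    motivation_sd: float = 2.6
    class_spec: list[LatentClassSpec] = field(default_factory=default_class_spec)
    arm_slope_logodds: Mapping[str, float] = field(
        default_factory=lambda: {"control": -0.05,
                                 "promillekoll": -0.0796,
                                 "partyplanner": -0.0696})
    response_rate_by_wave: tuple[float, float, float] = (0.78, 0.62, 0.65)
    mar_coef: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_students < 1:
            raise ConfigurationError("n_students must be >= 1")
        ratio = np.asarray(self.arm_ratio, dtype=float)
        if ratio.shape != (3,) or np.any(ratio < 0) or ratio.sum() <= 0:
            raise ConfigurationError(
                "arm_ratio must be 3 nonnegative weights with positive sum")
        for name, frac in [("prop_women", self.prop_women),
                           *[(f"response_rate_by_wave[{i}]", r)
                             for i, r in enumerate(self.response_rate_by_wave)]]:
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"{name}={frac} not in [0, 1]")
        if len(self.response_rate_by_wave) != N_WAVES - 1:
            raise ConfigurationError(
                f"response_rate_by_wave must have {N_WAVES - 1} entries "
                "(follow-up waves only; the baseline wave is always observed)")
        if not self.class_spec:
            raise ConfigurationError("class_spec must contain at least one class")
        total = sum(c.prevalence for c in self.class_spec)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"class prevalences sum to {total}, expected 1")
        if sum(c.frequent_heavy for c in self.class_spec) > 1:
            raise ConfigurationError(
                "at most one class may be flagged frequent_heavy")
        for arm in ARMS:
            if arm not in self.arm_slope_logodds:
                raise ConfigurationError(f"arm_slope_logodds missing arm {arm!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["weight_mean_by_gender"] = dict(self.weight_mean_by_gender)
        d["weight_sd_by_gender"] = dict(self.weight_sd_by_gender)
        d["arm_slope_logodds"] = dict(self.arm_slope_logodds)
        d["mar_coef"] = dict(self.mar_coef)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "class_spec" in d:
            d["class_spec"] = [
                c if isinstance(c, LatentClassSpec) else LatentClassSpec(**c)
                for c in d["class_spec"]
            ]
        if "arm_ratio" in d:
            d["arm_ratio"] = tuple(d["arm_ratio"])
        if "response_rate_by_wave" in d:
            d["response_rate_by_wave"] = tuple(d["response_rate_by_wave"])
        return cls(**d)
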