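"""Synthetic cohort generator.

Produces a cohort table, per-wave drinking diaries, arm and add-on
assignments, and wave-level missingness with the statistical structure the
downstream latent-state analysis assumes, so that every pipeline stage is
testable without access to participant data.

Cohort table columns: ``student_id, gender, age, weight_kg, audit,
motivation, arm, addon_arm, true_class``.  Diary table columns (long
format, 28 rows per student): ``student_id, wave, weekday, drinks, hours``;
a wave dropped by nonresponse has all 7 ``drinks``/``hours`` entries
missing (NaN).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import poisson

from .config import (ARMS, DAYS_PER_WEEK, N_WAVES, SEQ_LEN, ConfigurationError,
                     LatentClassSpec, SimConfig)
from .outcomes import is_excessive

__all__ = ["simulate_cohort", "assign_arms", "assign_addon",
           "apply_missingness", "SimulatedCohort", "ztp_rate_from_mean",
           "sample_ztp", "diaries_to_sequences"]


def ztp_rate_from_mean(mean: float) -> float:
    """Invert the zero-truncated-Poisson mean ``m = lam / (1 - exp(-lam))``.

    The ZTP mean is strictly greater than 1 for any positive rate; means at
    or below 1 map to a vanishing rate (all mass on a single drink).
    """
    if mean <= 1.0 + 1e-9:
        return 1e-6
    # m <= lam + 1 always, so lam in [m - 1, m] brackets the root.
    f = lambda lam: lam / (1.0 - np.exp(-lam)) - mean
    return brentq(f, max(mean - 1.0, 1e-12), mean, xtol=1e-12)


def sample_ztp(rate: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw zero-truncated Poisson counts by inverse transform."""
    if size == 0:
        return np.zeros(0, dtype=int)
    lo = poisson.cdf(0, rate)
    u = rng.uniform(lo, 1.0, size=size)
    return poisson.ppf(u, rate).astype(int)


@dataclass
class SimulatedCohort:
    """A simulated cohort with its generative ground truth.

    Attributes
    ----------
    students : pandas.DataFrame
        One row per student (covariates, arms, true class).
    diaries : pandas.DataFrame
        Long-format diary, 28 rows per student.
    day_class : numpy.ndarray of shape (n_students, 28)
        The latent class index occupied on each of the 28 diary days
        (simulation truth; not available to the analysis).
    class_labels : tuple of str
        Labels indexing ``day_class`` and ``true_class``.
    config : SimConfig
    """

    students: pd.DataFrame
    diaries: pd.DataFrame
    day_class: np.ndarray
    class_labels: tuple
    config: SimConfig

    def __iter__(self):
        # allows ``students, diaries = simulate_cohort(cfg)``
        return iter((self.students, self.diaries))


def assign_arms(students: pd.DataFrame, ratio=(1, 1, 1),
                seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Block-randomize students to the three trial arms.

    Arm counts follow the ratio exactly up to integer rounding (largest
    remainders get the spare slots), so a 1:1:1 ratio on a divisible n
    gives exactly equal arms.  Returns a copy with the ``arm`` column set.
    """
    ratio = np.asarray(ratio, dtype=float)
    if ratio.shape != (3,) or np.any(ratio < 0) or ratio.sum() <= 0:
        raise ConfigurationError("ratio must be 3 nonnegative weights, not all 0")
    students = students.copy()
    n = len(students)
    if n == 0:
        students["arm"] = pd.Series(dtype=object)
        return students
    target = n * ratio / ratio.sum()
    counts = np.floor(target).astype(int)
    remainder = target - counts
    # ties broken toward the lower arm index for determinism
    for idx in np.argsort(-remainder, kind="stable")[: n - counts.sum()]:
        counts[idx] += 1
    labels = np.repeat(ARMS, counts)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    students["arm"] = rng.permutation(labels)
    return students


def assign_addon(students: pd.DataFrame, diaries: pd.DataFrame,
                 seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Assign the nested add-on arms.

    App-arm students whose observed 7-week (wave 1) diary shows excessive
    weekly drinking (>9 drinks for women, >14 for men) are split 1:1 into
    ``telecoach`` / ``waitlist``.  Control-arm students excessive at
    baseline become ``assessment_control``.  Everyone else keeps ``none``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    students = students.copy()
    students["addon_arm"] = "none"
    weekly = (diaries.groupby(["student_id", "wave"])["drinks"]
              .sum(min_count=DAYS_PER_WEEK).unstack("wave"))
    gender = students.set_index("student_id")["gender"]

    def _excessive_at(wave: int) -> pd.Series:
        if wave not in weekly.columns:
            return pd.Series(False, index=weekly.index)
        q = weekly[wave]
        return pd.Series(
            [q.notna().loc[sid] and is_excessive(q.loc[sid], gender.loc[sid])
             for sid in weekly.index], index=weekly.index)

    exc_w1 = _excessive_at(1)
    exc_base = _excessive_at(0)

    app_mask = students["arm"].isin(["promillekoll", "partyplanner"])
    eligible = students.loc[
        app_mask & students["student_id"].map(exc_w1).fillna(False),
        "student_id"].to_numpy()
    if len(eligible):
        perm = rng.permutation(len(eligible))
        half = len(eligible) - len(eligible) // 2  # extra slot to telecoach
        tele = set(eligible[perm[:half]])
        wait = set(eligible[perm[half:]])
        students.loc[students["student_id"].isin(tele), "addon_arm"] = "telecoach"
        students.loc[students["student_id"].isin(wait), "addon_arm"] = "waitlist"

    ctrl_mask = (students["arm"] == "control") & \
        students["student_id"].map(exc_base).fillna(False)
    students.loc[ctrl_mask, "addon_arm"] = "assessment_control"
    return students


def apply_missingness(diaries: pd.DataFrame, students: pd.DataFrame,
                      response_rate_by_wave=(0.78, 0.62, 0.65),
                      seed: int | np.random.Generator = 0,
                      mar_coef: dict | None = None) -> pd.DataFrame:
    """Drop follow-up waves at random (MAR), whole weeks at a time.

    Each post-baseline wave is observed independently with the configured
    probability; ``mar_coef`` maps cohort columns to log-odds coefficients
    applied to the standardized covariate, so missingness may depend on
    observed baseline variables only (missing at random).  The baseline
    wave is never dropped.
    """
    rates = np.asarray(response_rate_by_wave, dtype=float)
    if np.any(rates < 0) or np.any(rates > 1):
        raise ConfigurationError("response rates must lie in [0, 1]")
    if rates.shape != (N_WAVES - 1,):
        raise ConfigurationError(f"expected {N_WAVES - 1} follow-up rates")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    diaries = diaries.copy()
    ids = students["student_id"].to_numpy()
    n = len(ids)

    shift = np.zeros(n)
    for col, coef in (mar_coef or {}).items():
        x = pd.to_numeric(students[col], errors="coerce").to_numpy(dtype=float)
        sd = np.nanstd(x)
        if sd > 0:
            shift = shift + coef * (x - np.nanmean(x)) / sd
    for w, rate in enumerate(rates, start=1):
        if rate <= 0.0:
            prob = np.zeros(n)
        elif rate >= 1.0:
            prob = np.ones(n)
        else:
            prob = expit(logit(rate) + shift)
        dropped = ids[rng.random(n) >= prob]
        mask = diaries["wave"].eq(w) & diaries["student_id"].isin(dropped)
        diaries.loc[mask, ["drinks", "hours"]] = np.nan
    return diaries


def _simulate_day_classes(home: np.ndarray, persistence: np.ndarray,
                          n_classes: int, rng: np.random.Generator) -> np.ndarray:
    """Latent pattern occupied each day: a sticky Markov chain over classes.

    Students start in their own class and keep their current behavioural
    pattern each day with that class's ``state_persistence``; switching
    moves them to a uniformly random other class, whose persistence then
    governs them in turn.  Switches are lasting behavioural changes, not
    day trips — a member of a pattern who switches away is what makes
    them itinerant rather than continual.
    """
    n = home.size
    states = np.empty((n, SEQ_LEN), dtype=int)
    states[:, 0] = home
    for t in range(1, SEQ_LEN):
        cur = states[:, t - 1]
        stay = rng.random(n) < persistence[cur]
        nxt = cur.copy()
        move = ~stay
        if n_classes > 1 and move.any():
            offs = rng.integers(0, n_classes - 1, size=int(move.sum()))
            nxt[move] = np.where(offs >= cur[move], offs + 1, offs)
        states[:, t] = nxt
    return states


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort (deterministic given ``config.seed``).

    Students are assigned a latent class by prevalence, covariates with
    class-specific shifts, and trial arms by block randomization.  Each of
    the 28 diary days then draws a drinking indicator from the occupied
    class's weekday profile, shifted by ``arm_slope_logodds[arm] * wave``
    on the log-odds scale, and a zero-truncated Poisson quantity given
    drinking.  Occasion duration defaults to ``max(1, drinks / 2)`` hours.
    Follow-up waves are then dropped per ``response_rate_by_wave`` and the
    add-on arms assigned from the post-missingness diaries.
    """
    rng = np.random.default_rng(config.seed)
    streams = rng.spawn(5)  # covariates, arms, diaries, missingness, addon
    r_cov, r_arm, r_diary, r_miss, r_addon = streams
    n = config.n_students
    classes = config.class_spec
    labels = tuple(c.label for c in classes)
    n_classes = len(classes)

    prev = np.array([c.prevalence for c in classes])
    home = r_cov.choice(n_classes, size=n, p=prev / prev.sum())

    male_shift = np.array([c.male_logodds_shift for c in classes])[home]
    p_w = expit(logit(np.clip(config.prop_women, 1e-12, 1 - 1e-12)) - male_shift)
    gender = np.where(r_cov.random(n) < p_w, "W", "M")

    age_shift = np.array([c.age_shift for c in classes])[home]
    age = np.maximum(18.0, r_cov.normal(config.age_mean + age_shift,
                                        config.age_sd, size=n))
    wmean = np.array([config.weight_mean_by_gender[g] for g in gender])
    wsd = np.array([config.weight_sd_by_gender[g] for g in gender])
    weight = np.maximum(45.0, r_cov.normal(wmean, wsd))

    audit_shift = np.array([c.audit_shift for c in classes])[home]
    audit = np.clip(np.rint(r_cov.normal(config.audit_mean + audit_shift,
                                         config.audit_sd, size=n)),
                    0, 40).astype(int)
    motiv_shift = np.array([c.motivation_shift for c in classes])[home]
    motivation = np.clip(np.rint(r_cov.normal(
        config.motivation_mean + motiv_shift, config.motivation_sd, size=n)),
        0, 10).astype(int)

    students = pd.DataFrame({
        "student_id": [f"S{i:05d}" for i in range(n)],
        "gender": gender,
        "age": np.round(age, 1),
        "weight_kg": np.round(weight, 1),
        "audit": audit,
        "motivation": motivation,
        "true_class": [labels[c] for c in home],
    })
    students = assign_arms(students, config.arm_ratio, seed=r_arm)
    students["addon_arm"] = "none"

    persistence = np.array([c.state_persistence for c in classes])
    day_class = _simulate_day_classes(home, persistence, n_classes, r_diary)

    day_probs = np.array([c.drink_prob_by_weekday for c in classes])  # (C, 7)
    arm_slope = np.array([config.arm_slope_logodds[a] for a in students["arm"]])
    weekday = np.tile(np.arange(DAYS_PER_WEEK), N_WAVES)           # (28,)
    wave_of_day = np.repeat(np.arange(N_WAVES), DAYS_PER_WEEK)     # (28,)

    base_p = day_probs[day_class, weekday[None, :]]                # (n, 28)
    with np.errstate(divide="ignore"):
        lo = np.log(base_p) - np.log1p(-base_p)                    # +-inf at 0/1
    shifted = expit(lo + arm_slope[:, None] * wave_of_day[None, :])
    shifted = np.where(base_p <= 0.0, 0.0, np.where(base_p >= 1.0, 1.0, shifted))
    drinking = r_diary.random((n, SEQ_LEN)) < shifted

    drinks = np.zeros((n, SEQ_LEN), dtype=float)
    rates = np.array([ztp_rate_from_mean(c.quantity_mean_given_drinking)
                      for c in classes])
    for c in range(n_classes):
        sel = drinking & (day_class == c)
        k = int(sel.sum())
        if k:
            drinks[sel] = sample_ztp(rates[c], k, r_diary)
    hours = np.where(drinks > 0, np.maximum(1.0, drinks / 2.0), np.nan)

    diaries = pd.DataFrame({
        "student_id": np.repeat(students["student_id"].to_numpy(), SEQ_LEN),
        "wave": np.tile(wave_of_day, n),
        "weekday": np.tile(weekday, n),
        "drinks": drinks.ravel(),
        "hours": hours.ravel(),
    })

    diaries = apply_missingness(diaries, students,
                                config.response_rate_by_wave,
                                seed=r_miss, mar_coef=dict(config.mar_coef))
    students = assign_addon(students, diaries, seed=r_addon)
    cols = ["student_id", "gender", "age", "weight_kg", "audit",
            "motivation", "arm", "addon_arm", "true_class"]
    return SimulatedCohort(students[cols], diaries, day_class, labels, config)


def diaries_to_sequences(diaries: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Pivot the long diary into an (n_students, 28) observation matrix.

    Returns ``(sequences, student_ids)``; position ``7 * wave + weekday``
    holds the day's drink count, NaN where unobserved.  Student order is
    the order of first appearance in the diary.
    """
    d = diaries.copy()
    d["pos"] = d["wave"].to_numpy() * DAYS_PER_WEEK + d["weekday"].to_numpy()
    ids = d["student_id"].drop_duplicates().to_numpy()
    wide = d.pivot_table(index="student_id", columns="pos", values="drinks",
                         dropna=False, aggfunc="first").reindex(ids)
    if wide.shape[1] != SEQ_LEN:
        missing_cols = sorted(set(range(SEQ_LEN)) - set(wide.columns))
        for c in missing_cols:
            wide[c] = np.nan
        wide = wide[sorted(wide.columns)]
        warnings.warn(f"diary missing day positions {missing_cols}; padded NaN")
    return wide.to_numpy(dtype=float), ids
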