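"""Interpretation of a fitted drinking-state HMM.

Labels states by the calendar weekday they occupy, identifies the
frequent-heavy state (drinks most days of the week with a very sticky
self-transition), classifies students as continual / itinerant members of
that state, compares the frequent-heavy group against the rest of the
cohort (Welch t-tests for continuous baseline variables, pooled
two-proportion Z-tests for binary ones), and estimates arm-wise trends in
the daily drinking probability by cluster-robust logistic regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .config import DAYS_PER_WEEK, WEEKDAYS
from .hmm import HmmParameters, HurdleHMMResults

__all__ = ["StateLabel", "FrequentHeavyReport", "label_states",
           "identify_frequent_heavy", "classify_membership",
           "compare_groups", "welch_t", "two_proportion_z",
           "drinking_trend", "TrendResult"]

FH_MIN_DRINK_DAYS = 3.5     # expected drinking days/week to call a state FH
FH_MIN_SELF_TRANS = 0.5     # minimum self-transition of the FH state
WEEKDAY_SHARE_MIN = 0.5     # occupancy share needed for a weekday label


@dataclass
class StateLabel:
    """A state's label with the evidence behind it."""

    state_index: int
    label: str                              # weekday name, frequent_heavy, unlabeled
    weekday_share: np.ndarray               # occupancy share by weekday (sums to 1)
    expected_drink_days: float              # 7 * p_k
    self_transition: float

    def to_dict(self) -> dict:
        return {"state_index": self.state_index, "label": self.label,
                "weekday_share": np.asarray(self.weekday_share).tolist(),
                "expected_drink_days": self.expected_drink_days,
                "self_transition": self.self_transition}


def identify_frequent_heavy(params: HmmParameters,
                            min_drink_days: float = FH_MIN_DRINK_DAYS,
                            min_self_transition: float = FH_MIN_SELF_TRANS):
    """Index of the frequent-heavy state, or None if no state qualifies.

    Qualifying states drink at least ``min_drink_days`` expected days per
    week (7 * p_k) with self-transition at least ``min_self_transition``;
    among them the largest 7 * p_k wins, ties going to the larger
    self-transition.
    """
    days = 7.0 * params.p
    self_tr = np.diag(params.transition)
    ok = np.flatnonzero((days >= min_drink_days)
                        & (self_tr >= min_self_transition))
    if ok.size == 0:
        return None
    order = sorted(ok, key=lambda k: (days[k], self_tr[k]), reverse=True)
    return int(order[0])


def _occupancy_shares(paths: np.ndarray, observed: np.ndarray | None,
                      k_states: int) -> np.ndarray:
    """Decoded-occupancy share of each weekday per state, shape (K, 7)."""
    T = paths.shape[1]
    weekday = np.arange(T) % DAYS_PER_WEEK
    if observed is None:
        observed = np.ones_like(paths, dtype=bool)
    shares = np.zeros((k_states, DAYS_PER_WEEK))
    for k in range(k_states):
        hit = (paths == k) & observed
        counts = np.array([hit[:, weekday == d].sum()
                           for d in range(DAYS_PER_WEEK)], dtype=float)
        total = counts.sum()
        shares[k] = counts / total if total > 0 else np.full(DAYS_PER_WEEK,
                                                             1.0 / DAYS_PER_WEEK)
    return shares


def label_states(params: HmmParameters, paths: np.ndarray,
                 observed: np.ndarray | None = None,
                 fh_kwargs: dict | None = None) -> list[StateLabel]:
    """Label every state: frequent-heavy first, then by dominant weekday.

    A state whose maximal weekday occupancy share (positions mod 7,
    Monday-first) is below 0.5 stays ``unlabeled``.  ``paths`` are decoded
    Viterbi paths, shape (n_students, T); ``observed`` optionally masks
    missing days out of the occupancy counts.
    """
    paths = np.asarray(paths)
    if paths.size == 0:
        raise ValueError("no decodings supplied")
    K = params.k_states
    fh = identify_frequent_heavy(params, **(fh_kwargs or {}))
    shares = _occupancy_shares(paths, observed, K)
    out = []
    for k in range(K):
        if k == fh:
            lab = "frequent_heavy"
        else:
            d = int(shares[k].argmax())
            lab = WEEKDAYS[d] if shares[k, d] >= WEEKDAY_SHARE_MIN else "unlabeled"
        out.append(StateLabel(k, lab, shares[k], float(7.0 * params.p[k]),
                              float(params.transition[k, k])))
    return out


def classify_membership(paths: np.ndarray, observed: np.ndarray,
                        fh_state: int) -> np.ndarray:
    """Per-student membership of the frequent-heavy state.

    ``continual``: every observed decoded day is the FH state.
    ``itinerant``: some observed days FH, some another state.
    ``non_member``: never decoded into FH.
    ``excluded``: no observed days at all (flagged with a warning).
    """
    paths = np.asarray(paths)
    observed = np.asarray(observed, dtype=bool)
    n = paths.shape[0]
    out = np.empty(n, dtype=object)
    n_excluded = 0
    for i in range(n):
        obs = observed[i]
        if not obs.any():
            out[i] = "excluded"
            n_excluded += 1
            continue
        in_fh = paths[i, obs] == fh_state
        if in_fh.all():
            out[i] = "continual"
        elif in_fh.any():
            out[i] = "itinerant"
        else:
            out[i] = "non_member"
    if n_excluded:
        warnings.warn(f"{n_excluded} student(s) with zero observed days "
                      "excluded from membership classification")
    return out


# --------------------------------------------------------------- group tests

def welch_t(x1, x2):
    """Welch two-sample t statistic, Welch-Satterthwaite df, two-sided p."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    x1, x2 = x1[~np.isnan(x1)], x2[~np.isnan(x2)]
    if len(x1) < 2 or len(x2) < 2:
        return None
    res = scipy.stats.ttest_ind(x1, x2, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def two_proportion_z(count1: int, n1: int, count2: int, n2: int):
    """Pooled two-proportion Z statistic and two-sided p-value.

    Z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled proportion.
    """
    if n1 == 0 or n2 == 0:
        return None
    p1, p2 = count1 / n1, count2 / n2
    pool = (count1 + count2) / (n1 + n2)
    se = np.sqrt(pool * (1.0 - pool) * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    return float(z), float(2.0 * scipy.stats.norm.sf(abs(z)))


CONTINUOUS_VARS = ("age", "audit", "quantity", "frequency", "binge_occasions",
                   "weekly_mean_ebac", "peak_ebac_month", "motivation")
BINARY_VARS = ("male", "excessive")


def compare_groups(baseline: pd.DataFrame, member_mask,
                   continuous=CONTINUOUS_VARS,
                   binary=BINARY_VARS) -> pd.DataFrame:
    """Compare total frequent-heavy members against everyone else.

    ``baseline`` holds one row per student with baseline covariates and
    outcomes; ``member_mask`` marks the frequent-heavy group.  Continuous
    variables get Welch t-tests, binary ones pooled two-proportion
    Z-tests; group 1 is the frequent-heavy group throughout, so positive
    statistics mean larger in that group.  Groups too small for a t-test
    are flagged with a missing statistic.
    """
    member_mask = np.asarray(member_mask, dtype=bool)
    g1 = baseline.loc[member_mask]
    g2 = baseline.loc[~member_mask]
    rows = []
    for var in continuous:
        if var not in baseline.columns:
            continue
        res = welch_t(g1[var], g2[var])
        rows.append({
            "variable": var, "test": "welch_t",
            "group1_mean": float(np.nanmean(g1[var])) if len(g1) else np.nan,
            "group2_mean": float(np.nanmean(g2[var])) if len(g2) else np.nan,
            "statistic": res[0] if res else np.nan,
            "df": res[1] if res else np.nan,
            "p_value": res[2] if res else np.nan,
            "flagged": res is None,
        })
    for var in binary:
        if var not in baseline.columns:
            continue
        v1 = g1[var].dropna().astype(bool)
        v2 = g2[var].dropna().astype(bool)
        res = two_proportion_z(int(v1.sum()), len(v1), int(v2.sum()), len(v2))
        rows.append({
            "variable": var, "test": "two_proportion_z",
            "group1_mean": v1.mean() if len(v1) else np.nan,
            "group2_mean": v2.mean() if len(v2) else np.nan,
            "statistic": res[0] if res else np.nan,
            "df": np.nan,
            "p_value": res[1] if res else np.nan,
            "flagged": res is None,
        })
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- trends

@dataclass
class TrendResult:
    """Arm-contrast trend in daily drinking probability.

    ``odds_ratio`` multiplies the per-wave change in drinking odds for the
    contrast arm relative to the reference arm (the exponentiated
    wave-by-arm interaction from a day-level logistic regression with
    student-clustered robust standard errors).
    """

    reference_arm: str
    contrast_arm: str
    odds_ratio: float | None
    se_log_or: float | None
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    n_students: int
    n_days: int
    flagged: bool = False
    reason: str | None = None
    proportions: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("reference_arm", "contrast_arm", "odds_ratio", "se_log_or",
              "ci_low", "ci_high", "p_value", "n_students", "n_days",
              "flagged", "reason")}
        return d


def drinking_trend(diaries: pd.DataFrame, students: pd.DataFrame,
                   reference_arm: str, contrast_arm: str,
                   member_ids=None, arm_col: str = "arm",
                   waves=None) -> TrendResult:
    """Arm contrast on the per-wave trend of the daily drinking probability.

    Fits, by maximum likelihood, ``drink ~ wave + arm + wave:arm`` at the
    day level (one Bernoulli observation per observed diary day) within
    the given membership stratum, with cluster-robust (by student)
    covariance, and returns the interaction odds ratio with its 95% CI.
    Also carries the per-wave drinking proportions by arm for plotting.
    ``waves`` restricts the analysis to a subset of waves (the nested
    add-on contrasts use waves 1-3 only).
    """
    info = students.set_index("student_id")
    d = diaries.dropna(subset=["drinks"]).copy()
    d["arm_val"] = d["student_id"].map(info[arm_col])
    if member_ids is not None:
        d = d[d["student_id"].isin(set(member_ids))]
    d = d[d["arm_val"].isin([reference_arm, contrast_arm])]
    if waves is not None:
        d = d[d["wave"].isin(list(waves))]

    def _flag(reason):
        return TrendResult(reference_arm, contrast_arm, None, None, None,
                           None, None, d["student_id"].nunique(), len(d),
                           flagged=True, reason=reason)

    if d.empty:
        return _flag("empty stratum")
    d["drink"] = (d["drinks"] > 0).astype(float)
    d["is_contrast"] = (d["arm_val"] == contrast_arm).astype(float)
    props = (d.groupby(["arm_val", "wave"])["drink"].mean()
             .rename("prop_drinking").reset_index())
    n_arms = d["arm_val"].nunique()
    if n_arms < 2:
        return _flag("only one arm present")
    if d["drink"].nunique() < 2:
        return _flag("no outcome variation (all-zero or all-drinking stratum)")

    X = sm.add_constant(pd.DataFrame({
        "wave": d["wave"].astype(float),
        "contrast": d["is_contrast"],
        "wave_x_contrast": d["wave"].astype(float) * d["is_contrast"],
    }))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(d["drink"], X, family=sm.families.Binomial()).fit(
                cov_type="cluster",
                cov_kwds={"groups": d["student_id"].to_numpy()})
        b = fit.params["wave_x_contrast"]
        se = fit.bse["wave_x_contrast"]
        if not (np.isfinite(b) and np.isfinite(se)) or se > 50:
            return _flag("separation (unstable interaction estimate)")
        zc = scipy.stats.norm.ppf(0.975)
        res = TrendResult(
            reference_arm, contrast_arm,
            odds_ratio=float(np.exp(b)), se_log_or=float(se),
            ci_low=float(np.exp(b - zc * se)),
            ci_high=float(np.exp(b + zc * se)),
            p_value=float(fit.pvalues["wave_x_contrast"]),
            n_students=d["student_id"].nunique(), n_days=len(d))
    except Exception as exc:
        return _flag(f"fit failed: {exc}")
    res.proportions = props
    return res


@dataclass
class FrequentHeavyReport:
    """Full frequent-heavy characterization: members, comparisons, trends."""

    fh_state_index: int | None
    membership: pd.DataFrame                 # student_id, membership
    group_stats: pd.DataFrame | None
    trend_results: list = field(default_factory=list)
    state_labels: list = field(default_factory=list)

    @property
    def n_continual(self) -> int:
        return int((self.membership["membership"] == "continual").sum())

    @property
    def n_itinerant(self) -> int:
        return int((self.membership["membership"] == "itinerant").sum())

    @property
    def n_members(self) -> int:
        return self.n_continual + self.n_itinerant

    def to_dict(self) -> dict:
        return {
            "fh_state_index": self.fh_state_index,
            "n_continual": self.n_continual,
            "n_itinerant": self.n_itinerant,
            "n_members": self.n_members,
            "state_labels": [s.to_dict() for s in self.state_labels],
            "group_stats": (self.group_stats.to_dict(orient="records")
                            if self.group_stats is not None else None),
            "trend_ors": [t.to_dict() for t in self.trend_results],
        }
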