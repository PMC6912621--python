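"""Synthetic cohort generator: determinism, marginals, arm logic, missingness."""

import numpy as np
import pandas as pd
import pytest

from drinkstates import (SimConfig, apply_missingness, assign_addon,
                         assign_arms, diaries_to_sequences, simulate_cohort)
from drinkstates.config import ConfigurationError, LatentClassSpec
from drinkstates.simulate import sample_ztp, ztp_rate_from_mean


def flat_config(**kw):
    cls = LatentClassSpec("only", 1.0, kw.pop("probs", (0.3,) * 7),
                          kw.pop("qmean", 2.5),
                          state_persistence=1.0)
    base = dict(n_students=50, class_spec=[cls],
                arm_slope_logodds={"control": 0.0, "promillekoll": 0.0,
                                   "partyplanner": 0.0},
                response_rate_by_wave=(1.0, 1.0, 1.0), seed=0)
    base.update(kw)
    return SimConfig(**base)


class TestZtp:
    def test_rate_inversion_roundtrip(self):
        for m in (1.5, 2.0, 3.6, 8.0):
            lam = ztp_rate_from_mean(m)
            assert lam / (1 - np.exp(-lam)) == pytest.approx(m, abs=1e-9)

    def test_samples_are_positive_with_requested_mean(self):
        rng = np.random.default_rng(0)
        x = sample_ztp(ztp_rate_from_mean(3.0), 20000, rng)
        assert x.min() >= 1
        assert x.mean() == pytest.approx(3.0, abs=0.05)


class TestSimulateCohort:
    def test_determinism_bit_identical(self):
        cfg = SimConfig(n_students=80, seed=123)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a.students, b.students)
        pd.testing.assert_frame_equal(a.diaries, b.diaries)
        assert np.array_equal(a.day_class, b.day_class)

    def test_zero_probability_class_never_drinks(self):
        sim = simulate_cohort(flat_config(probs=(0.0,) * 7, n_students=10,
                                          seed=42))
        assert sim.diaries["drinks"].eq(0).all()
        assert len(sim.diaries) == 10 * 28

    def test_forced_drinking_every_day(self):
        sim = simulate_cohort(flat_config(probs=(1.0,) * 7, n_students=10,
                                          seed=1))
        assert (sim.diaries["drinks"] >= 1).all()
        assert (sim.diaries.loc[sim.diaries["drinks"] > 0, "hours"] > 0).all()

    def test_invalid_prevalences_rejected(self):
        bad = [LatentClassSpec("a", 0.6, (0.1,) * 7, 2.0),
               LatentClassSpec("b", 0.6, (0.1,) * 7, 2.0)]
        with pytest.raises(ConfigurationError):
            SimConfig(n_students=5, class_spec=bad)

    def test_two_frequent_heavy_classes_rejected(self):
        bad = [LatentClassSpec("a", 0.5, (0.5,) * 7, 2.0, frequent_heavy=True),
               LatentClassSpec("b", 0.5, (0.5,) * 7, 2.0, frequent_heavy=True)]
        with pytest.raises(ConfigurationError):
            SimConfig(n_students=5, class_spec=bad)

    def test_marginals_within_three_standard_errors(self):
        n = 8000
        cfg = SimConfig(n_students=n, seed=17)
        sim = simulate_cohort(cfg)
        pw = (sim.students["gender"] == "W").mean()
        # gender: FH male shift moves the overall proportion only ~0.07 * shift
        assert abs(pw - 0.675) < 3 * np.sqrt(0.675 * 0.325 / n) + 0.02
        prev = sim.students["true_class"].value_counts(normalize=True)
        for c in cfg.class_spec:
            se = np.sqrt(c.prevalence * (1 - c.prevalence) / n)
            assert abs(prev.get(c.label, 0.0) - c.prevalence) < 3 * se + 1e-9
        # per-wave response fractions
        obs = sim.diaries.groupby("wave")["drinks"].apply(
            lambda s: s.notna().mean())
        for w, rate in enumerate(cfg.response_rate_by_wave, start=1):
            se = np.sqrt(rate * (1 - rate) / n)
            assert abs(obs[w] - rate) < 3 * se

    def test_zero_slopes_give_flat_drinking_trend(self):
        sim = simulate_cohort(flat_config(n_students=4000, probs=(0.4,) * 7,
                                          seed=9))
        by_wave = sim.diaries.assign(drink=sim.diaries["drinks"] > 0) \
            .groupby("wave")["drink"].mean()
        assert by_wave.max() - by_wave.min() < 0.03

    def test_frequent_heavy_drinking_days_near_configured_expectation(self):
        """FH members at p=0.65/day drink ~4.55 days/week (within 0.3)."""
        cfg = SimConfig(n_students=10000, seed=21,
                        arm_slope_logodds={"control": 0.0, "promillekoll": 0.0,
                                           "partyplanner": 0.0},
                        response_rate_by_wave=(1.0, 1.0, 1.0))
        sim = simulate_cohort(cfg)
        fh = sim.students.loc[sim.students["true_class"] == "frequent_heavy",
                              "student_id"]
        d = sim.diaries[sim.diaries["student_id"].isin(set(fh))]
        days_per_week = d.groupby(["student_id", "wave"])["drinks"] \
            .apply(lambda s: (s > 0).sum()).mean()
        assert days_per_week == pytest.approx(4.55, abs=0.3)

    def test_mean_drinking_days_matches_monte_carlo_oracle(self):
        """Frequency oracle: small-cohort FH mean vs. a large-n direct draw.

        The oracle simulates the FH day-class chain and weekday profile
        directly (no diary machinery) at n=100000 students-weeks.
        """
        cfg = SimConfig(n_students=2000, seed=1,
                        arm_slope_logodds={"control": 0.0, "promillekoll": 0.0,
                                           "partyplanner": 0.0},
                        response_rate_by_wave=(1.0, 1.0, 1.0))
        sim = simulate_cohort(cfg)
        fh_ids = set(sim.students.loc[
            sim.students["true_class"] == "frequent_heavy", "student_id"])
        d = sim.diaries[sim.diaries["student_id"].isin(fh_ids)]
        observed = d.groupby(["student_id", "wave"])["drinks"] \
            .apply(lambda s: (s > 0).sum()).mean()

        # independent oracle: day-class chain + Bernoulli draws
        rng = np.random.default_rng(999)
        classes = cfg.class_spec
        fh_idx = next(i for i, c in enumerate(classes) if c.frequent_heavy)
        probs = np.array([c.drink_prob_by_weekday for c in classes])
        pers = np.array([c.state_persistence for c in classes])
        n_mc, C = 25000, len(classes)        # 25000 students x 4 weeks = 1e5
        state = np.full(n_mc, fh_idx)
        drink_days = np.zeros(n_mc)
        for t in range(28):
            if t > 0:
                move = rng.random(n_mc) >= pers[state]
                k = int(move.sum())
                if k:
                    offs = rng.integers(0, C - 1, size=k)
                    state[move] = np.where(offs >= state[move], offs + 1, offs)
            drink_days += rng.random(n_mc) < probs[state, t % 7]
        oracle = drink_days.mean() / 4.0
        assert observed == pytest.approx(oracle, abs=0.3)


class TestAssignArms:
    def test_exact_division(self):
        students = pd.DataFrame({"student_id": [f"s{i}" for i in range(6)]})
        out = assign_arms(students, (1, 1, 1), seed=0)
        assert out["arm"].value_counts().eq(2).all()

    def test_trial_scale_split(self):
        students = pd.DataFrame({"student_id": [f"s{i}" for i in range(2166)]})
        out = assign_arms(students, (1, 1, 1), seed=1)
        assert out["arm"].value_counts().eq(722).all()

    def test_degenerate_ratio_sends_all_to_control(self):
        students = pd.DataFrame({"student_id": list("abcd")})
        out = assign_arms(students, (1, 0, 0), seed=0)
        assert (out["arm"] == "control").all()

    def test_counts_differ_by_at_most_one(self):
        students = pd.DataFrame({"student_id": [f"s{i}" for i in range(100)]})
        counts = assign_arms(students, (1, 1, 1), seed=2)["arm"].value_counts()
        assert counts.max() - counts.min() <= 1

    def test_empty_input(self):
        out = assign_arms(pd.DataFrame({"student_id": []}), (1, 1, 1), seed=0)
        assert len(out) == 0


class TestAssignAddon:
    @staticmethod
    def _cohort_and_diaries(weekly_by_student, genders, arms):
        students = pd.DataFrame({
            "student_id": list(weekly_by_student),
            "gender": genders, "arm": arms})
        rows = []
        for sid, weekly in weekly_by_student.items():
            for w in range(4):
                total = weekly.get(w)
                for d in range(7):
                    drinks = (np.nan if total is None
                              else (total if d == 0 else 0))
                    rows.append({"student_id": sid, "wave": w, "weekday": d,
                                 "drinks": drinks,
                                 "hours": 1.0 if drinks and drinks > 0 else np.nan})
        return students, pd.DataFrame(rows)

    def test_gendered_eligibility_cutoffs(self):
        students, diaries = self._cohort_and_diaries(
            {"w10": {0: 0, 1: 10, 2: 0, 3: 0},    # woman, 10/wk: eligible
             "m14": {0: 0, 1: 14, 2: 0, 3: 0}},   # man, 14/wk: not eligible
            genders=["W", "M"], arms=["promillekoll", "partyplanner"])
        out = assign_addon(students, diaries, seed=0)
        got = out.set_index("student_id")["addon_arm"]
        assert got["w10"] in ("telecoach", "waitlist")
        assert got["m14"] == "none"

    def test_even_split_of_eligible(self):
        weekly = {f"s{i}": {0: 0, 1: 20, 2: 0, 3: 0} for i in range(4)}
        students, diaries = self._cohort_and_diaries(
            weekly, genders=["M"] * 4, arms=["promillekoll"] * 4)
        out = assign_addon(students, diaries, seed=3)
        counts = out["addon_arm"].value_counts()
        assert counts.get("telecoach", 0) == 2
        assert counts.get("waitlist", 0) == 2

    def test_control_arm_baseline_excessive_becomes_assessment_control(self):
        students, diaries = self._cohort_and_diaries(
            {"c1": {0: 20, 1: 0, 2: 0, 3: 0},
             "c2": {0: 2, 1: 30, 2: 0, 3: 0}},
            genders=["M", "M"], arms=["control", "control"])
        out = assign_addon(students, diaries, seed=0)
        got = out.set_index("student_id")["addon_arm"]
        assert got["c1"] == "assessment_control"
        assert got["c2"] == "none"     # control arm: wave-1 status irrelevant

    def test_missing_wave1_diary_not_eligible(self):
        students, diaries = self._cohort_and_diaries(
            {"s": {0: 0, 1: None, 2: 0, 3: 0}},
            genders=["M"], arms=["promillekoll"])
        out = assign_addon(students, diaries, seed=0)
        assert out["addon_arm"].iloc[0] == "none"


class TestMissingness:
    def _sim(self):
        return simulate_cohort(flat_config(n_students=200, seed=2))

    def test_full_response_leaves_everything_observed(self):
        sim = self._sim()
        out = apply_missingness(sim.diaries, sim.students, (1.0, 1.0, 1.0),
                                seed=0)
        assert out["drinks"].notna().all()

    def test_zero_response_drops_all_followups_but_not_baseline(self):
        sim = self._sim()
        out = apply_missingness(sim.diaries, sim.students, (0.0, 0.0, 0.0),
                                seed=0)
        assert out.loc[out["wave"] == 0, "drinks"].notna().all()
        assert out.loc[out["wave"] > 0, "drinks"].isna().all()

    def test_whole_wave_dropped_jointly(self):
        sim = self._sim()
        out = apply_missingness(sim.diaries, sim.students, (0.5, 0.5, 0.5),
                                seed=4)
        per_wave = out.groupby(["student_id", "wave"])["drinks"] \
            .apply(lambda s: s.isna().sum())
        assert per_wave.isin([0, 7]).all()

    def test_observed_fraction_concentrates_on_rate(self):
        sim = simulate_cohort(flat_config(n_students=5000, seed=2))
        out = apply_missingness(sim.diaries, sim.students, (0.7, 0.7, 0.7),
                                seed=3)
        frac = out.loc[out["wave"] == 1, "drinks"].notna().mean()
        assert frac == pytest.approx(0.7, abs=0.02)

    def test_rate_outside_unit_interval_rejected(self):
        sim = self._sim()
        with pytest.raises(ConfigurationError):
            apply_missingness(sim.diaries, sim.students, (1.2, 0.5, 0.5))


def test_sequence_matrix_shape_and_content(small_cohort):
    seqs, ids = diaries_to_sequences(small_cohort.diaries)
    assert seqs.shape == (len(small_cohort.students), 28)
    assert list(ids) == list(small_cohort.students["student_id"])
    row = small_cohort.diaries[small_cohort.diaries["student_id"] == ids[0]]
    expected = row.sort_values(["wave", "weekday"])["drinks"].to_numpy()
    assert np.array_equal(seqs[0], expected, equal_nan=True)
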