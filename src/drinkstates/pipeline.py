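"""End-to-end analysis pipeline.

Stages: simulate (or read) a cohort -> derive weekly outcomes -> fit HMMs
over a K range and pick the BIC minimizer -> label states, identify the
frequent-heavy group, compare it to the rest of the cohort, and estimate
arm-wise drinking-probability trends.  Every random draw derives from the
single configured seed, so a report is reproducible bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .config import ConfigurationError, SEQ_LEN, SimConfig
from .ebac import WidmarkConstants
from .hmm import select_states
from .io import read_cohort, read_diaries
from .outcomes import BINGE_THRESHOLD, outcomes_table
from .simulate import diaries_to_sequences, simulate_cohort
from .states import (FrequentHeavyReport, classify_membership, compare_groups,
                     drinking_trend, identify_frequent_heavy, label_states)

__all__ = ["PipelineConfig", "AnalysisReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Pipeline configuration: simulation mode or file inputs, plus settings."""

    sim: SimConfig | None = None
    cohort_path: str | None = None
    diary_path: str | None = None
    widmark: WidmarkConstants = field(default_factory=WidmarkConstants)
    binge_thresholds: dict = field(default_factory=lambda: dict(BINGE_THRESHOLD))
    k_range: tuple = tuple(range(2, 13))
    n_restarts: int = 20
    tol: float = 1e-6
    maxiter: int = 500
    fh_min_drink_days: float = 3.5
    fh_min_self_transition: float = 0.5
    seed: int = 0

    def __post_init__(self):
        file_mode = self.cohort_path is not None or self.diary_path is not None
        if self.sim is not None and file_mode:
            raise ConfigurationError(
                "configure either simulation mode or input paths, not both")
        if self.sim is None and (self.cohort_path is None
                                 or self.diary_path is None):
            raise ConfigurationError(
                "need a SimConfig or both cohort_path and diary_path")
        ks = list(self.k_range)
        if not ks or any(b <= a for a, b in zip(ks, ks[1:])):
            raise ConfigurationError("k_range must be nonempty and increasing")


@dataclass
class AnalysisReport:
    """Everything the pipeline computed, JSON-serializable via to_dict()."""

    cohort_summary: dict
    outcome_summary: pd.DataFrame
    bic_by_k: dict
    best_k: int
    fit_summary: dict
    fh_report: FrequentHeavyReport
    sequence_length: int
    config_echo: dict
    seed: int
    version: str = __version__
    students: pd.DataFrame | None = field(default=None, repr=False)
    diaries: pd.DataFrame | None = field(default=None, repr=False)
    outcomes: pd.DataFrame | None = field(default=None, repr=False)
    best_fit: object | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "config_echo": self.config_echo,
            "sequence_length": self.sequence_length,
            "cohort_summary": self.cohort_summary,
            "outcome_summary": self.outcome_summary.to_dict(orient="records"),
            "bic_by_k": {str(k): v for k, v in self.bic_by_k.items()},
            "best_k": self.best_k,
            "fit_summary": self.fit_summary,
            "frequent_heavy": self.fh_report.to_dict(),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True,
                          default=_jsonify)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def _config_echo(config: PipelineConfig) -> dict:
    d = {
        "mode": "simulate" if config.sim is not None else "files",
        "k_range": list(config.k_range),
        "n_restarts": config.n_restarts,
        "tol": config.tol,
        "maxiter": config.maxiter,
        "fh_min_drink_days": config.fh_min_drink_days,
        "fh_min_self_transition": config.fh_min_self_transition,
        "binge_thresholds": dict(config.binge_thresholds),
        "widmark": {"r_by_gender": dict(config.widmark.r_by_gender),
                    "beta": config.widmark.beta,
                    "grams_per_standard_drink":
                        config.widmark.grams_per_standard_drink,
                    "output_scale": config.widmark.output_scale},
        "seed": config.seed,
    }
    if config.sim is not None:
        sim = config.sim.to_dict()
        sim["class_spec"] = [c["label"] for c in sim["class_spec"]]
        d["sim"] = sim
    else:
        d["cohort_path"] = str(config.cohort_path)
        d["diary_path"] = str(config.diary_path)
    return d


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Run every stage and assemble the report.

    Stage failures surface as exceptions tagged with the stage name.
    """
    stage = "inputs"
    try:
        if config.sim is not None:
            sim = simulate_cohort(config.sim)
            students, diaries = sim.students, sim.diaries
        else:
            students = read_cohort(config.cohort_path)
            diaries = read_diaries(config.diary_path)

        stage = "outcomes"
        out = outcomes_table(students, diaries, config.widmark,
                             config.binge_thresholds)
        outcome_summary = (out.groupby("wave")
                           [["quantity", "frequency", "binge_occasions",
                             "weekly_mean_ebac", "peak_ebac_month"]]
                           .mean().round(4).reset_index())

        stage = "hmm_selection"
        seqs, ids = diaries_to_sequences(diaries)
        ss = np.random.SeedSequence(config.seed)
        hmm_seed = int(ss.generate_state(1)[0] % (2 ** 31))
        best, all_fits = select_states(
            seqs, config.k_range, n_restarts=config.n_restarts,
            seed=hmm_seed, tol=config.tol, maxiter=config.maxiter)

        stage = "state_analysis"
        paths = best.viterbi_paths()
        observed = ~np.isnan(seqs)
        fh_kwargs = {"min_drink_days": config.fh_min_drink_days,
                     "min_self_transition": config.fh_min_self_transition}
        labels = label_states(best.params, paths, observed,
                              fh_kwargs=fh_kwargs)
        fh_idx = identify_frequent_heavy(best.params, **fh_kwargs)
        if fh_idx is not None:
            membership = classify_membership(paths, observed, fh_idx)
        else:
            membership = np.full(len(ids), "non_member", dtype=object)
        member_df = pd.DataFrame({"student_id": ids, "membership": membership})

        baseline = _baseline_table(students, out)
        member_mask = baseline["student_id"].map(
            member_df.set_index("student_id")["membership"]).isin(
                ["continual", "itinerant"]).to_numpy()
        stats = compare_groups(baseline, member_mask) if member_mask.any() else None

        member_ids = member_df.loc[
            member_df["membership"].isin(["continual", "itinerant"]),
            "student_id"]
        trends = []
        if fh_idx is not None and len(member_ids):
            trends.append(drinking_trend(diaries, students, "promillekoll",
                                         "control", member_ids))
            trends.append(drinking_trend(diaries, students, "promillekoll",
                                         "partyplanner", member_ids))
            trends.append(drinking_trend(diaries, students, "telecoach",
                                         "assessment_control", member_ids,
                                         arm_col="addon_arm", waves=(1, 2, 3)))
        fh_report = FrequentHeavyReport(fh_idx, member_df, stats, trends,
                                        labels)

        stage = "report"
        cohort_summary = {
            "n_students": int(len(students)),
            "arm_counts": students["arm"].value_counts().to_dict(),
            "addon_counts": students["addon_arm"].value_counts().to_dict(),
            "prop_women": float((students["gender"] == "W").mean()),
            "mean_age": float(students["age"].mean()),
            "mean_audit": float(students["audit"].mean()),
        }
        return AnalysisReport(
            cohort_summary=cohort_summary,
            outcome_summary=outcome_summary,
            bic_by_k={k: (None if r is None else float(r.bic))
                      for k, r in all_fits.items()},
            best_k=best.k_states,
            fit_summary=best.to_dict(),
            fh_report=fh_report,
            sequence_length=int(seqs.shape[1]),
            config_echo=_config_echo(config),
            seed=config.seed,
            students=students, diaries=diaries, outcomes=out, best_fit=best)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _baseline_table(students: pd.DataFrame, outcomes: pd.DataFrame) -> pd.DataFrame:
    base = outcomes[outcomes["wave"] == 0].set_index("student_id")
    df = students.copy()
    for col in ("quantity", "frequency", "binge_occasions",
                "weekly_mean_ebac", "peak_ebac_month", "excessive"):
        df[col] = df["student_id"].map(base[col])
    df["male"] = (df["gender"] == "M").astype(float)
    return df
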