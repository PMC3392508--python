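"""End-to-end study pipeline: data in, validity report out.

Orchestrates the full construct-validity analysis the way a skills-lab
study would run it: generate (or load) per-trial data, compute MAPs, compare
the expert and novice groups (overall Hotelling T² plus nine per-MAP
ANOVAs), fit the logistic skill classifier, rank MAP contributions by Wald
statistic, and score resubstitution accuracy.  Questionnaire tables get the
companion analysis: per-item Mann–Whitney on raw 5-point scores and
χ²/Fisher on scores dichotomised into low–moderate (1–3) vs high (4–5).

File dialects (all UTF-8, ``.`` decimal):

* tracking log, one file per trial:
  ``time_s,hand,tilt1_deg,tilt2_deg,depth_mm,roll_deg`` with hand ∈ {L, R},
  rows sorted by (hand, time_s);
* MAP table: ``trial_id,group,l_path_mm,l_depth_mm,l_area_deg2,l_volume_mm3,
  r_path_mm,r_depth_mm,r_area_deg2,r_volume_mm3,time_s``;
* Likert table (long format): ``respondent_id,group,item,score``.

Reports are written as one JSON document plus CSV side-tables; a partial
report is never written — any stage failure aborts with the failing stage
named.  Display rounding follows the conventional journal style: one
decimal for percentages, two for p-values, with p < 0.005 printed "<0.01".
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .motion_metrics import MAP_NAMES, MAPVector, TrialMetrics, compute_trial_maps
from .skill_classifier import (
    ClassificationSummary,
    LabeledCohort,
    LogisticModel,
    fit_logistic,
    resubstitution_summary,
    wald_statistics,
)
from .synthetic_motion import (
    GroupMAPParams,
    SkillProfile,
    expert_profile,
    knot_task_reference_params,
    novice_profile,
    sample_map_cohort,
    simulate_trajectory_pair,
)
from .trocar_kinematics import TrackingSample, Trajectory
from .validity_stats import TestResult, chi_square_test, compare_all_maps, fisher_exact, mann_whitney_u

__all__ = [
    "StudyConfig",
    "ValidityReport",
    "run_construct_validity",
    "run_questionnaire_analysis",
    "read_tracking_csv",
    "write_tracking_csv",
    "read_map_table",
    "write_map_table",
    "write_report",
    "validate_report_dict",
    "format_p",
]

log = logging.getLogger("lapskill")

TRACKING_HEADER = ["time_s", "hand", "tilt1_deg", "tilt2_deg", "depth_mm", "roll_deg"]
MAP_TABLE_HEADER = ["trial_id", "group"] + [
    "l_path_mm", "l_depth_mm", "l_area_deg2", "l_volume_mm3",
    "r_path_mm", "r_depth_mm", "r_area_deg2", "r_volume_mm3", "time_s",
]
_MAP_COLS = MAP_TABLE_HEADER[2:]


def format_p(p: float, floor: float = 0.005) -> str:
    """Journal-style p-value: two decimals, '<0.01' below 0.005."""
    if p < floor:
        return "<0.01"
    return f"{p:.2f}"


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------

class FormatError(ValueError):
    """Malformed input file; message carries the offending line number."""


def write_tracking_csv(left: Trajectory, right: Trajectory, path) -> None:
    """Write one trial's two-hand tracking log."""
    rows = []
    for hand_code, traj in (("L", left), ("R", right)):
        for s in traj.samples:
            rows.append((s.t, hand_code, s.tilt1, s.tilt2, s.depth, s.roll))
    df = pd.DataFrame(rows, columns=TRACKING_HEADER)
    df.to_csv(path, index=False, float_format="%.9g")


def read_tracking_csv(path, fs: float = 100.0) -> tuple[Trajectory, Trajectory]:
    """Read a tracking log; returns ``(left, right)`` trajectories.

    Raises :class:`FormatError` with a line number for a malformed header,
    an unknown hand code, or a non-numeric field; raises if either hand is
    absent.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as e:  # noqa: BLE001 - rewrap with file context
        raise FormatError(f"{path}: cannot parse CSV ({e})") from e
    if list(df.columns) != TRACKING_HEADER:
        raise FormatError(
            f"{path}:1: bad header {list(df.columns)!r}, expected {TRACKING_HEADER!r}"
        )
    bad_hand = ~df["hand"].isin(["L", "R"])
    if bad_hand.any():
        i = int(np.flatnonzero(bad_hand)[0])
        raise FormatError(f"{path}:{i + 2}: unknown hand code {df['hand'].iloc[i]!r}")
    for col in TRACKING_HEADER:
        if col == "hand":
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            i = int(np.flatnonzero(vals.isna())[0])
            raise FormatError(f"{path}:{i + 2}: non-numeric value in column {col!r}")
        df[col] = vals

    out = {}
    for code, hand in (("L", "left"), ("R", "right")):
        sub = df[df["hand"] == code].sort_values("time_s")
        if len(sub) == 0:
            raise FormatError(f"{path}: no samples for hand {code!r}")
        samples = [
            TrackingSample(t=r.time_s, tilt1=r.tilt1_deg, tilt2=r.tilt2_deg,
                           depth=r.depth_mm, roll=r.roll_deg)
            for r in sub.itertuples(index=False)
        ]
        out[hand] = Trajectory(hand=hand, samples=samples, fs=fs)
    return out["left"], out["right"]


def write_map_table(trials: Sequence[TrialMetrics], path) -> None:
    rows = [
        {"trial_id": t.trial_id, "group": t.group,
         **dict(zip(_MAP_COLS, t.maps.as_array()))}
        for t in trials
    ]
    pd.DataFrame(rows, columns=MAP_TABLE_HEADER).to_csv(path, index=False,
                                                        float_format="%.9g")


def read_map_table(path) -> list[TrialMetrics]:
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != MAP_TABLE_HEADER:
        raise FormatError(
            f"{path}:1: bad header {list(df.columns)!r}, expected {MAP_TABLE_HEADER!r}"
        )
    if df["trial_id"].duplicated().any():
        dup = df["trial_id"][df["trial_id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate trial_id {dup!r}")
    return [
        TrialMetrics(
            trial_id=str(r.trial_id), group=str(r.group),
            maps=MAPVector.from_array([getattr(r, c) for c in _MAP_COLS]),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Everything a reproducible construct-validity run needs.

    ``tier`` selects the generator: ``'map-level'`` draws per-trial MAP
    vectors straight from the group distributions; ``'trajectory'``
    simulates raw 4-DOF motion and computes MAPs from it.  ``map_params``
    defaults to the knot-task reference distributions;
    ``profiles`` to the default novice/expert motion profiles.
    """

    seed: int = 0
    tier: str = "map-level"
    n_novice: int | None = None  # None -> the params' own cohort sizes
    n_expert: int | None = None
    map_params: tuple | None = None  # (GroupMAPParams novice, GroupMAPParams expert)
    profiles: tuple | None = None  # (SkillProfile novice, SkillProfile expert)
    variant: str = "pooled"
    alpha: float = 0.05
    holm: bool = False
    ridge: float = 1e-4
    tol: float = 1e-8
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.tier not in ("map-level", "trajectory"):
            raise ValueError(f"tier must be map-level|trajectory, got {self.tier!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def echo(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()
             if k not in ("map_params", "profiles")}
        d["map_params"] = None if self.map_params is None else [
            {"label": p.label, "n": p.n, "means": list(p.means), "sds": list(p.sds)}
            for p in self.map_params
        ]
        d["profiles"] = None if self.profiles is None else [
            asdict(p) for p in self.profiles
        ]
        return d


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class ValidityReport:
    """Structured analysis output mirroring the standard report tables."""

    map_comparison: pd.DataFrame
    hotelling: TestResult
    wald_table: pd.DataFrame
    classification: ClassificationSummary
    model: LogisticModel
    likert: pd.DataFrame | None
    provenance: dict

    def to_dict(self) -> dict:
        cmp_rows = self.map_comparison.to_dict(orient="records")
        for row in cmp_rows:
            row["p_display"] = format_p(row["p"])
        c = self.classification
        return {
            "map_comparison": cmp_rows,
            "hotelling": {
                "statistic": self.hotelling.statistic,
                "statistic_name": self.hotelling.statistic_name,
                "df": list(np.atleast_1d(self.hotelling.df).astype(float)),
                "p": self.hotelling.p,
                "method": self.hotelling.method,
            },
            "wald_table": self.wald_table.to_dict(orient="records"),
            "classification": {
                "correct_novice": c.correct_novice, "total_novice": c.total_novice,
                "correct_expert": c.correct_expert, "total_expert": c.total_expert,
                "pct_novice": c.pct_novice, "pct_expert": c.pct_expert,
                "pct_overall": c.pct_overall,
            },
            "model": {
                "beta": list(self.model.beta), "se": list(self.model.se),
                "ridge": self.model.ridge, "converged": self.model.converged,
                "scaling": {"mean": list(self.model.scaling[0]),
                            "sd": list(self.model.scaling[1])},
            },
            "likert": None if self.likert is None else self.likert.to_dict(orient="records"),
            "provenance": self.provenance,
        }


_REPORT_REQUIRED = {
    "map_comparison": list,
    "hotelling": dict,
    "wald_table": list,
    "classification": dict,
    "model": dict,
    "provenance": dict,
}


def validate_report_dict(d: Mapping) -> list[str]:
    """Structural check of a serialized report; returns problem strings
    (empty = valid).  Mirrors the JSON schema shipped as
    ``report_schema.json``."""
    problems = []
    for key, typ in _REPORT_REQUIRED.items():
        if key not in d:
            problems.append(f"missing key {key!r}")
        elif not isinstance(d[key], typ):
            problems.append(f"key {key!r} has type {type(d[key]).__name__}, "
                            f"expected {typ.__name__}")
    if not problems:
        if len(d["map_comparison"]) != len(MAP_NAMES):
            problems.append("map_comparison must have 9 rows")
        if len(d["wald_table"]) != len(MAP_NAMES):
            problems.append("wald_table must have 9 rows")
        c = d["classification"]
        need = {"correct_novice", "total_novice", "correct_expert",
                "total_expert", "pct_overall"}
        missing = need - set(c)
        if missing:
            problems.append(f"classification missing {sorted(missing)}")
        else:
            recomputed = round(
                100.0 * (c["correct_novice"] + c["correct_expert"])
                / (c["total_novice"] + c["total_expert"]), 1)
            if abs(recomputed - c["pct_overall"]) > 1e-9:
                problems.append("pct_overall inconsistent with counts")
    return problems


def write_report(report: ValidityReport, out_dir) -> dict:
    """Write report JSON plus CSV side-tables; returns the paths written.

    All content is assembled before any file is touched, so a failure never
    leaves a partial report behind.
    """
    out_dir = Path(out_dir)
    payload = json.dumps(report.to_dict(), indent=2, default=float)
    cmp_csv = report.map_comparison.to_csv(index=False)
    wald_csv = report.wald_table.to_csv(index=False)
    likert_csv = None if report.likert is None else report.likert.to_csv(index=False)

    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"report": out_dir / "report.json",
             "map_comparison": out_dir / "map_comparison.csv",
             "wald": out_dir / "wald_table.csv"}
    paths["report"].write_text(payload)
    paths["map_comparison"].write_text(cmp_csv)
    paths["wald"].write_text(wald_csv)
    if likert_csv is not None:
        paths["likert"] = out_dir / "likert_comparison.csv"
        paths["likert"].write_text(likert_csv)
    return paths


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as e:
                raise StageError(f"stage {name!r} failed: {e}") from e
        return wrapper
    return deco


@_stage("generate")
def _generate_trials(config: StudyConfig) -> tuple[list[TrialMetrics], list[TrialMetrics]]:
    ss = np.random.SeedSequence(config.seed)
    if config.tier == "map-level":
        nov_p, exp_p = config.map_params or knot_task_reference_params()
        if config.n_novice is not None:
            nov_p = GroupMAPParams(label=nov_p.label, n=config.n_novice,
                                   means=nov_p.means, sds=nov_p.sds)
        if config.n_expert is not None:
            exp_p = GroupMAPParams(label=exp_p.label, n=config.n_expert,
                                   means=exp_p.means, sds=exp_p.sds)
        s_nov, s_exp = ss.spawn(2)
        return sample_map_cohort(nov_p, s_nov), sample_map_cohort(exp_p, s_exp)

    nov_prof, exp_prof = config.profiles or (novice_profile(), expert_profile())
    n_nov = config.n_novice if config.n_novice is not None else 59
    n_exp = config.n_expert if config.n_expert is not None else 56
    trials_nov, trials_exp = [], []
    seeds = ss.spawn(n_nov + n_exp)
    for i in range(n_nov):
        left, right = simulate_trajectory_pair(nov_prof, seeds[i])
        trials_nov.append(compute_trial_maps(left, right, f"novice-{i:03d}", "novice"))
    for i in range(n_exp):
        left, right = simulate_trajectory_pair(exp_prof, seeds[n_nov + i])
        trials_exp.append(compute_trial_maps(left, right, f"expert-{i:03d}", "expert"))
    return trials_nov, trials_exp


@_stage("compare")
def _compare(config, novice, expert):
    return compare_all_maps(novice, expert, variant=config.variant, holm=config.holm)


@_stage("classify")
def _classify(config, novice, expert):
    cohort = LabeledCohort.from_trials(list(novice) + list(expert))
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = fit_logistic(cohort, ridge=config.ridge, tol=config.tol)
    notes = [str(w.message) for w in caught]
    summary = resubstitution_summary(model, cohort, threshold=config.threshold)
    return model, wald_statistics(model), summary, notes


def run_construct_validity(config: StudyConfig,
                           novice: Sequence[TrialMetrics] | None = None,
                           expert: Sequence[TrialMetrics] | None = None,
                           ) -> ValidityReport:
    """Run the full construct-validity analysis.

    Pass ``novice``/``expert`` trial lists to analyse measured data;
    otherwise cohorts are generated per the config (tier, params, seed).
    The run is a pure function of (config, data): identical inputs give an
    identical report.
    """
    if (novice is None) != (expert is None):
        raise ValueError("provide both cohorts or neither")
    if novice is None:
        novice, expert = _generate_trials(config)
    hotelling, cmp_table = _compare(config, novice, expert)
    model, wald_table, summary, notes = _classify(config, novice, expert)
    provenance = {
        "package": "lapskill",
        "version": _pkg_version,
        "config": config.echo(),
        "n_novice": len(novice),
        "n_expert": len(expert),
        "warnings": notes,
    }
    return ValidityReport(
        map_comparison=cmp_table,
        hotelling=hotelling,
        wald_table=wald_table,
        classification=summary,
        model=model,
        likert=None,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# questionnaire analysis
# ---------------------------------------------------------------------------

def run_questionnaire_analysis(likert: pd.DataFrame,
                               groups: tuple = ("expert", "trainee"),
                               ) -> pd.DataFrame:
    """Per-item group comparison of 5-point questionnaire responses.

    For each item: group means/SDs, a two-sided Mann–Whitney p on the raw
    scores, and — after dichotomising scores into low–moderate (1–3) vs
    high (4–5) — a χ² p, replaced by Fisher's exact test whenever any
    expected cell count is below 5.
    """
    need = {"respondent_id", "group", "item", "score"}
    if not need <= set(likert.columns):
        raise ValueError(f"Likert table must have columns {sorted(need)}")
    scores = likert["score"]
    if not scores.between(1, 5).all() or not (scores == scores.astype(int)).all():
        raise ValueError("scores must be integers in 1..5")
    g_a, g_b = groups
    rows = []
    for item, sub in likert.groupby("item", sort=False):
        xa = sub.loc[sub["group"] == g_a, "score"].to_numpy()
        xb = sub.loc[sub["group"] == g_b, "score"].to_numpy()
        if len(xa) == 0 or len(xb) == 0:
            raise ValueError(f"item {item!r} missing responses for a group")
        mw = mann_whitney_u(xa, xb)
        # dichotomise: 1-3 low-moderate, 4-5 high
        table = np.array([
            [(xa <= 3).sum(), (xa >= 4).sum()],
            [(xb <= 3).sum(), (xb >= 4).sum()],
        ])
        if (table.sum(axis=0) == 0).any():
            cat_p, cat_method = np.nan, "undefined"
        else:
            expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
            if (expected < 5).any():
                res = fisher_exact(table)
                cat_p, cat_method = res.p, "fisher"
            else:
                res = chi_square_test(table)
                cat_p, cat_method = res.p, "chi2"
        rows.append({
            "item": item,
            f"{g_a}_n": len(xa), f"{g_a}_mean": float(xa.mean()),
            f"{g_a}_sd": float(xa.std(ddof=1)) if len(xa) > 1 else 0.0,
            f"{g_b}_n": len(xb), f"{g_b}_mean": float(xb.mean()),
            f"{g_b}_sd": float(xb.std(ddof=1)) if len(xb) > 1 else 0.0,
            f"{g_a}_pct_high": float(100.0 * (xa >= 4).mean()),
            f"{g_b}_pct_high": float(100.0 * (xb >= 4).mean()),
            "mw_p": mw.p,
            "dichotomized_p": cat_p,
            "dichotomized_method": cat_method,
        })
    return pd.DataFrame(rows)
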