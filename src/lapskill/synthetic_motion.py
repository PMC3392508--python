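"""Synthetic cohorts for the skill-assessment pipeline.

The raw recordings behind published box-trainer validation studies are
rarely deposited; what is printed are group-level summaries (per-MAP means
and SDs for novices and experts) and questionnaire score distributions.
This module provides three generator tiers so every downstream stage can be
exercised end-to-end:

1. **MAP-level cohorts** (:func:`sample_map_cohort`) — per-trial feature
   vectors drawn from independent truncated normals parameterised by the
   published group means/SDs.  :func:`knot_task_reference_params` ships the
   knot-tying-task reference distributions (59 novices, 56 experts).
2. **Trajectory-level simulation** (:func:`simulate_trajectory_pair`) —
   100 Hz two-hand 4-DOF streams built from minimum-jerk point-to-point
   submovements plus band-limited physiological tremor, so that the
   kinematics and metric layers are tested on realistic smooth motion whose
   *computed* MAPs separate skill levels.
3. **Likert questionnaires** (:func:`sample_likert_cohort`) — 5-point
   ordinal responses with per-group score distributions, used by the
   face/content-validity analysis.

Truncated-normal parameterisation
---------------------------------
Sampling a normal and truncating at zero shifts the realised mean upward
whenever the mean is within a couple of SDs of zero (for the expert
left-path distribution the shift would be ~200 mm).  The generator therefore
*moment-matches*: it solves for the underlying normal's (μ, σ) such that the
zero-truncated distribution has exactly the requested mean and SD.  A
feasible solution exists whenever sd/mean < √(π/2 − 1)/√(2/π) ≈ 0.756 (the
half-normal limit), which holds for every reference distribution here.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .motion_metrics import MAP_NAMES, MAPVector, TrialMetrics
from .trocar_kinematics import TrackingSample, Trajectory

__all__ = [
    "SkillProfile",
    "GroupMAPParams",
    "LikertItemParams",
    "knot_task_reference_params",
    "novice_profile",
    "expert_profile",
    "sample_map_cohort",
    "simulate_trajectory_pair",
    "sample_likert_cohort",
    "likert_probs_from_mean_sd",
    "default_questionnaire_params",
]

#: Nominal instrument insertion at the workspace centre (mm past the pivot).
BASE_DEPTH_MM = 60.0

#: Centre frequency of simulated physiological tremor (Hz).
TREMOR_SMOOTH_SAMPLES = 9


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SkillProfile:
    """Generative parameters for one skill group's instrument motion.

    Parameters
    ----------
    label : str
        ``'novice'`` or ``'expert'``.
    n_submovements : int
        Number of point-to-point reaches composing the task.  Skilled
        operators need fewer corrective submovements.
    mean_speed : float
        Average tip speed during a reach (mm/s).
    tremor_sd : float
        RMS amplitude of band-limited tremor at the tip (mm).
    angular_span : float
        Half-range of each pivot tilt visited by reach targets (deg).
    depth_span : float
        Range of insertion depths visited by reach targets (mm).
    task_duration_cap : float
        Hard task time limit (s); recordings are cut at the cap.
    """

    label: str
    n_submovements: int
    mean_speed: float
    tremor_sd: float
    angular_span: float
    depth_span: float
    task_duration_cap: float = 300.0

    def __post_init__(self) -> None:
        if self.label not in ("novice", "expert"):
            raise ValueError(f"label must be novice|expert, got {self.label!r}")
        for name in ("n_submovements", "mean_speed", "task_duration_cap"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("tremor_sd", "angular_span", "depth_span"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def novice_profile(**overrides) -> SkillProfile:
    """Default novice motion profile: many corrective submovements, slower
    reaches, larger tremor and a wider visited workspace; tasks often run
    into the 300 s cap."""
    params = dict(
        label="novice",
        n_submovements=350,
        mean_speed=25.0,
        tremor_sd=0.08,
        angular_span=6.5,
        depth_span=30.0,
        task_duration_cap=300.0,
    )
    params.update(overrides)
    return SkillProfile(**params)


def expert_profile(**overrides) -> SkillProfile:
    """Default expert motion profile: fewer, faster, steadier reaches in a
    tighter workspace."""
    params = dict(
        label="expert",
        n_submovements=200,
        mean_speed=32.0,
        tremor_sd=0.02,
        angular_span=5.0,
        depth_span=18.0,
        task_duration_cap=300.0,
    )
    params.update(overrides)
    return SkillProfile(**params)


@dataclass(frozen=True)
class GroupMAPParams:
    """Marginal (mean, SD) of each MAP component for one group, plus cohort
    size.  Components are treated as independent: published tables print
    only marginal summaries, never the correlation structure."""

    label: str
    n: int
    means: tuple  # 9 floats, MAP_NAMES order
    sds: tuple  # 9 floats

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        if len(self.means) != 9 or len(self.sds) != 9:
            raise ValueError("means and sds must have 9 components")
        if any(s < 0 for s in self.sds):
            raise ValueError("sds must be non-negative")

    def mean(self, name: str) -> float:
        return self.means[MAP_NAMES.index(name)]

    def sd(self, name: str) -> float:
        return self.sds[MAP_NAMES.index(name)]


def knot_task_reference_params() -> tuple[GroupMAPParams, GroupMAPParams]:
    """Reference MAP distributions for the laparoscopic square-knot task.

    Group means and SDs observed for 59 novices and 56 experts on a
    box trainer with a 4-DOF trocar tracker; component order follows
    :data:`~lapskill.motion_metrics.MAP_NAMES`.
    """
    novices = GroupMAPParams(
        label="novice",
        n=59,
        means=(6288.47, 19.01, 142.53, 2746.13, 5780.33, 17.46, 104.40, 2170.82, 277.50),
        sds=(1994.74, 5.77, 86.24, 1790.54, 2096.37, 4.08, 51.52, 1128.60, 39.97),
    )
    experts = GroupMAPParams(
        label="expert",
        n=56,
        means=(2792.92, 16.19, 89.93, 1318.09, 2862.95, 14.98, 85.34, 1451.15, 117.59),
        sds=(1733.70, 4.05, 55.13, 870.48, 1587.96, 3.62, 40.48, 863.43, 77.80),
    )
    return novices, experts


# ---------------------------------------------------------------------------
# MAP-level cohorts
# ---------------------------------------------------------------------------

@lru_cache(maxsize=256)
def _truncnorm_underlying(target_mean: float, target_sd: float) -> tuple[float, float]:
    """Underlying normal (μ, σ) whose zero-truncation has the target moments."""
    if target_sd == 0.0:
        return target_mean, 0.0
    if target_mean <= 0.0:
        raise ValueError("target mean must be positive for a zero-truncated normal")

    def resid(q):
        mu, log_sig = q
        sig = math.exp(log_sig)
        a = (0.0 - mu) / sig
        d = stats.truncnorm(a, np.inf, loc=mu, scale=sig)
        return [d.mean() - target_mean, d.std() - target_sd]

    sol = least_squares(resid, x0=[target_mean, math.log(target_sd)], xtol=1e-14)
    mu, sig = sol.x[0], math.exp(sol.x[1])
    if max(abs(r) for r in resid(sol.x)) > 1e-6 * max(target_mean, target_sd):
        raise ValueError(
            f"cannot moment-match a zero-truncated normal to mean={target_mean}, "
            f"sd={target_sd} (coefficient of variation too large)"
        )
    return mu, sig


def sample_map_cohort(params: GroupMAPParams, seed) -> list[TrialMetrics]:
    """Draw a cohort of per-trial MAP vectors for one group.

    Each of the nine components is drawn independently from a zero-truncated
    normal moment-matched to the group's (mean, SD); every sampled component
    is therefore non-negative and the cohort's population moments equal the
    requested parameters exactly.  Reproducible given the seed.
    """
    rng = np.random.default_rng(seed)
    X = np.empty((params.n, 9))
    for j in range(9):
        m, s = params.means[j], params.sds[j]
        if s == 0.0:
            X[:, j] = m
            continue
        mu, sig = _truncnorm_underlying(m, s)
        a = (0.0 - mu) / sig
        X[:, j] = stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sig,
                                      size=params.n, random_state=rng)
    return [
        TrialMetrics(
            trial_id=f"{params.label}-{i:03d}",
            group=params.label,
            maps=MAPVector.from_array(X[i]),
        )
        for i in range(params.n)
    ]


# ---------------------------------------------------------------------------
# trajectory-level simulation
# ---------------------------------------------------------------------------

def _min_jerk_profile(n: int) -> np.ndarray:
    """Normalised minimum-jerk position profile 10τ³ − 15τ⁴ + 6τ⁵ on (0, 1]."""
    tau = np.arange(1, n + 1) / n
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _smooth_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Band-limited Gaussian tremor: white noise box-car filtered then
    rescaled to the requested RMS amplitude."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    k = TREMOR_SMOOTH_SAMPLES
    w = rng.standard_normal(n + k - 1)
    sm = np.convolve(w, np.ones(k) / k, mode="valid")
    return sm * (sd * math.sqrt(k))  # box-car reduces variance by k


def _simulate_hand(profile: SkillProfile, hand: str, rng: np.random.Generator,
                   fs: float) -> Trajectory:
    span_a = profile.angular_span
    span_d = profile.depth_span
    # waypoints in configuration space (tilt1 deg, tilt2 deg, depth mm)
    n_wp = profile.n_submovements + 1
    tilts = rng.uniform(-span_a, span_a, size=(n_wp, 2)) if span_a > 0 else np.zeros((n_wp, 2))
    depths = BASE_DEPTH_MM + (rng.uniform(0.0, span_d, size=n_wp) if span_d > 0 else np.zeros(n_wp))
    wp = np.column_stack([tilts, depths])

    # tip positions of waypoints, for distance-based submovement durations
    def tip(q):
        a, b = np.deg2rad(q[0]), np.deg2rad(q[1])
        d = q[2]
        return np.array([-d * np.cos(a) * np.sin(b), d * np.sin(a), -d * np.cos(a) * np.cos(b)])

    max_samples = int(round(profile.task_duration_cap * fs)) + 1
    segs = [wp[0][None, :]]
    total = 1
    for j in range(profile.n_submovements):
        dist = float(np.linalg.norm(tip(wp[j + 1]) - tip(wp[j])))
        dur = max(dist / profile.mean_speed, 0.12)  # floor: shortest human reach
        n = max(int(round(dur * fs)), 1)
        prof = _min_jerk_profile(n)[:, None]
        segs.append(wp[j] + prof * (wp[j + 1] - wp[j]))
        total += n
        if total >= max_samples:
            break
    q = np.vstack(segs)[:max_samples]

    n = len(q)
    # tremor: tip-equivalent mm mapped to tilt degrees at the nominal depth
    ang_sd = math.degrees(profile.tremor_sd / BASE_DEPTH_MM)
    q = q.copy()
    q[:, 0] += _smooth_noise(rng, n, ang_sd)
    q[:, 1] += _smooth_noise(rng, n, ang_sd)
    q[:, 2] = np.maximum(q[:, 2] + _smooth_noise(rng, n, profile.tremor_sd), 0.0)

    t = np.arange(n) / fs
    roll = np.cumsum(_smooth_noise(rng, n, 0.05))
    samples = [
        TrackingSample(t=float(t[i]), tilt1=float(q[i, 0]), tilt2=float(q[i, 1]),
                       depth=float(q[i, 2]), roll=float(roll[i]))
        for i in range(n)
    ]
    return Trajectory(hand=hand, samples=samples, fs=fs)


def simulate_trajectory_pair(profile: SkillProfile, seed,
                             fs: float = 100.0) -> tuple[Trajectory, Trajectory]:
    """Simulate one trial's two-hand 4-DOF streams.

    Each hand performs ``n_submovements`` minimum-jerk reaches between
    uniformly drawn targets inside the profile's angular/depth spans, with
    band-limited tremor superimposed; the recording stops at the task
    duration cap.  The two hands use independent random substreams but the
    same profile.  Returns ``(left, right)``.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    left_rng, right_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    left = _simulate_hand(profile, "left", left_rng, fs)
    right = _simulate_hand(profile, "right", right_rng, fs)
    return left, right


# ---------------------------------------------------------------------------
# Likert questionnaires
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LikertItemParams:
    """Per-group score distributions over the 5-point scale for one item."""

    item: str
    probs: Mapping[str, tuple]  # group -> 5 probabilities over scores 1..5

    def __post_init__(self) -> None:
        for g, p in self.probs.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (5,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"invalid probability vector for group {g!r}")

    def group_mean(self, group: str) -> float:
        return float(np.dot(self.probs[group], np.arange(1, 6)))

    def group_sd(self, group: str) -> float:
        p = np.asarray(self.probs[group], dtype=float)
        m = self.group_mean(group)
        return float(math.sqrt(np.dot(p, (np.arange(1, 6) - m) ** 2)))


def likert_probs_from_mean_sd(mean: float, sd: float) -> tuple:
    """Probability vector over scores 1..5 with (approximately) the given
    mean and SD, constructed as a discretised normal.

    A latent N(μ, σ) is binned at {1.5, 2.5, 3.5, 4.5} and (μ, σ) are solved
    so the discrete distribution's moments match the targets.  Published
    questionnaire tables print only means and SDs; this is the maximum-
    entropy-flavoured way to turn them back into score distributions.
    """
    if not 1.0 <= mean <= 5.0:
        raise ValueError("mean must lie in [1, 5]")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0.0:
        p = np.zeros(5)
        p[int(round(mean)) - 1] = 1.0
        return tuple(p)

    edges = np.array([-np.inf, 1.5, 2.5, 3.5, 4.5, np.inf])
    scores = np.arange(1, 6)

    def probs_of(mu, sig):
        cdf = stats.norm.cdf(edges, loc=mu, scale=sig)
        return np.diff(cdf)

    def resid(q):
        mu, log_sig = q
        p = probs_of(mu, math.exp(log_sig))
        m = np.dot(p, scores)
        v = np.dot(p, (scores - m) ** 2)
        return [m - mean, math.sqrt(v) - sd]

    sol = least_squares(resid, x0=[mean, math.log(max(sd, 0.2))], xtol=1e-13)
    p = probs_of(sol.x[0], math.exp(sol.x[1]))
    return tuple(p / p.sum())


def default_questionnaire_params() -> list[LikertItemParams]:
    """Reference face/content-validity item distributions for experts vs
    trainees, reconstructed from published per-group means and SDs of a
    box-trainer first-impression questionnaire."""
    table = [
        # item, expert (mean, sd), trainee (mean, sd)
        ("design", (3.36, 0.79), (3.88, 0.74)),
        ("realism", (3.30, 0.81), (3.29, 0.67)),
        ("user_friendliness", (3.68, 0.66), (3.71, 0.69)),
        ("overall_functionality", (3.08, 1.02), (3.88, 0.74)),
        ("trocar_positions", (3.78, 0.71), (3.79, 0.51)),
        ("instrument_movement", (3.70, 0.85), (3.63, 0.71)),
        ("procedural_functioning", (4.16, 0.68), (4.42, 0.56)),
        ("hand_eye_coordination", (4.29, 0.64), (4.35, 0.58)),
        ("depth_perception", (3.34, 0.95), (3.69, 1.02)),
    ]
    return [
        LikertItemParams(
            item=name,
            probs={
                "expert": likert_probs_from_mean_sd(*ex),
                "trainee": likert_probs_from_mean_sd(*tr),
            },
        )
        for name, ex, tr in table
    ]


def sample_likert_cohort(items: Sequence[LikertItemParams],
                         n_per_group: Mapping[str, int] | int,
                         seed) -> pd.DataFrame:
    """Sample a long-format questionnaire table.

    Returns a DataFrame with columns ``respondent_id, group, item, score``
    (scores are integers 1..5).  ``n_per_group`` is either a mapping
    ``group -> count`` or a single count applied to every group present in
    the item parameters.  Reproducible given the seed.
    """
    if not items:
        raise ValueError("no items given")
    groups = list(items[0].probs.keys())
    for it in items:
        if list(it.probs.keys()) != groups:
            raise ValueError("all items must define the same groups")
    if isinstance(n_per_group, int):
        n_per_group = {g: n_per_group for g in groups}

    rng = np.random.default_rng(seed)
    rows = []
    for g in groups:
        for i in range(n_per_group[g]):
            rid = f"{g}-{i:03d}"
            for it in items:
                score = int(rng.choice(np.arange(1, 6), p=np.asarray(it.probs[g])))
                rows.append((rid, g, it.item, score))
    return pd.DataFrame(rows, columns=["respondent_id", "group", "item", "score"])
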