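"""Motion analysis parameters (MAPs) for laparoscopic skill assessment.

Five task-efficiency metrics are computed per hand from the tracked
instrument motion:

* **path length** (mm) — arc length of the curve described by the tip;
* **insertion distance** (mm) — total travel of the instrument along its
  own axis, i.e. the total variation of the depth signal;
* **angular area** (deg²) — the tilt-space rectangle spanned by the two
  pivot angles (range of tilt1 × range of tilt2), a measure of how far
  apart the farthest instrument orientations were;
* **volume** (mm³) — convex-hull volume of the tip path, the
  three-dimensional space used;
* **time** (s) — task duration from timestamps.

The per-trial unit of analysis is the nine-component :class:`MAPVector`:
the four spatial metrics for each hand plus the (shared) task time, in a
fixed order matching the standard report layout.

Angular area is deliberately the axis-aligned bounding rectangle of the
tilt excursions — the simplest statistic with deg² units consistent with
"distance between the farthest positions"; the convex-hull area in tilt
space is available as an option.  Volume uses the convex hull rather than
a bounding box because "space used" most naturally means the occupied
hull; degenerate point sets (fewer than four points, or coplanar) have
zero volume rather than raising.

No smoothing is applied to raw samples before metric computation; an
optional moving-average filter is provided for noisy recordings but
defaults off.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .trocar_kinematics import Trajectory, TipPoint, tip_path_array

__all__ = [
    "MAPVector",
    "TrialMetrics",
    "MAP_NAMES",
    "path_length",
    "insertion_distance",
    "angular_area",
    "workspace_volume",
    "task_time",
    "compute_trial_maps",
    "moving_average",
]

#: Canonical component order of the per-trial feature vector.
MAP_NAMES = (
    "l_path",
    "l_depth",
    "l_area",
    "l_volume",
    "r_path",
    "r_depth",
    "r_area",
    "r_volume",
    "time",
)


@dataclass(frozen=True)
class MAPVector:
    """Nine-component per-trial feature vector (units: mm, mm, deg², mm³ per
    hand, then seconds).  All components are non-negative and finite."""

    l_path: float
    l_depth: float
    l_area: float
    l_volume: float
    r_path: float
    r_depth: float
    r_area: float
    r_volume: float
    time: float

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"MAP component {f.name} is not finite: {v!r}")
            if v < 0:
                raise ValueError(f"MAP component {f.name} is negative: {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in MAP_NAMES], dtype=float)

    @classmethod
    def from_array(cls, a: Iterable[float]) -> "MAPVector":
        a = np.asarray(list(a), dtype=float)
        if a.shape != (9,):
            raise ValueError(f"expected 9 components, got shape {a.shape}")
        return cls(*a.tolist())


@dataclass(frozen=True)
class TrialMetrics:
    """A trial's MAP vector together with its identity and group label."""

    trial_id: str
    group: str  # novice | expert | unknown
    maps: MAPVector

    def __post_init__(self) -> None:
        if self.group not in ("novice", "expert", "unknown"):
            raise ValueError(f"unknown group label {self.group!r}")


def _as_points(tip_path) -> np.ndarray:
    if isinstance(tip_path, np.ndarray):
        pts = np.asarray(tip_path, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"expected (n, 3) point array, got {pts.shape}")
    else:
        pts = np.array([p.as_array() if isinstance(p, TipPoint) else p for p in tip_path],
                       dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 3)
    if len(pts) == 0:
        raise ValueError("empty tip path")
    return pts


def path_length(tip_path) -> float:
    """Arc length (mm) of the tip curve: sum of consecutive segment lengths.

    Zero for a single point or a stationary path.
    """
    pts = _as_points(tip_path)
    if len(pts) == 1:
        return 0.0
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def insertion_distance(traj: Trajectory) -> float:
    """Total axial travel (mm): the total variation of the depth signal."""
    d = traj.depths
    if len(d) == 1:
        return 0.0
    return float(np.abs(np.diff(d)).sum())


def angular_area(traj: Trajectory, method: str = "range") -> float:
    """Angular workspace (deg²) spanned by the two pivot tilts.

    ``method='range'`` (default) is the bounding rectangle
    (max−min of tilt1) × (max−min of tilt2); ``method='hull'`` is the
    convex-hull area of the tilt scatter, always ≤ the rectangle.
    """
    tilts = traj.tilts
    if method == "range":
        spans = tilts.max(axis=0) - tilts.min(axis=0)
        return float(spans[0] * spans[1])
    if method == "hull":
        if len(tilts) < 3:
            return 0.0
        try:
            return float(ConvexHull(tilts).volume)  # 2-D hull "volume" is area
        except QhullError:
            return 0.0
    raise ValueError(f"unknown angular-area method {method!r}")


def workspace_volume(tip_path) -> float:
    """Convex-hull volume (mm³) of the tip points.

    Degenerate inputs — fewer than 4 points, or all points collinear or
    coplanar — occupy zero volume.
    """
    pts = _as_points(tip_path)
    if len(pts) < 4:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        # affinely degenerate (coplanar/collinear) point set
        return 0.0


def task_time(traj: Trajectory) -> float:
    """Task duration (s): last timestamp minus first.

    Computed from timestamps rather than sample count so that jittery or
    gapped recordings report wall-clock duration.
    """
    t = traj.times
    return float(t[-1] - t[0])


def moving_average(traj: Trajectory, window: int) -> Trajectory:
    """Optional box-car smoothing of the angle/depth channels (off by default
    in every pipeline; provided for noisy recordings)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1 or len(traj) <= 2:
        return traj
    from .trocar_kinematics import TrackingSample

    k = min(window, len(traj))
    kern = np.ones(k) / k

    def smooth(x: np.ndarray) -> np.ndarray:
        pad = np.concatenate([np.repeat(x[0], k - 1), x])
        return np.convolve(pad, kern, mode="valid")

    tilts = traj.tilts
    sm1, sm2 = smooth(tilts[:, 0]), smooth(tilts[:, 1])
    smd = np.maximum(smooth(traj.depths), 0.0)
    samples = [
        TrackingSample(t=s.t, tilt1=float(a), tilt2=float(b), depth=float(d), roll=s.roll)
        for s, a, b, d in zip(traj.samples, sm1, sm2, smd)
    ]
    return Trajectory(hand=traj.hand, samples=samples, fs=traj.fs)


def _hand_metrics(traj: Trajectory) -> tuple[float, float, float, float]:
    pts = tip_path_array(traj)
    return (
        path_length(pts),
        insertion_distance(traj),
        angular_area(traj),
        workspace_volume(pts),
    )


def compute_trial_maps(
    left: Trajectory,
    right: Trajectory,
    trial_id: str,
    group: str = "unknown",
) -> TrialMetrics:
    """Assemble the nine-component MAP vector for one two-handed trial.

    The four spatial metrics are computed independently per hand; the trial
    time is the longer of the two hands' durations (both hands record the
    same task, but one stream may start late or end early).  Disjoint time
    ranges indicate a logging fault and raise.
    """
    if left.hand != "left" or right.hand != "right":
        raise ValueError(
            f"expected (left, right) trajectories, got ({left.hand!r}, {right.hand!r})"
        )
    lt, rt = left.times, right.times
    if lt[-1] < rt[0] or rt[-1] < lt[0]:
        raise ValueError(
            "left and right hand recordings do not overlap in time; "
            "streams are probably from different trials"
        )
    l_path, l_depth, l_area, l_volume = _hand_metrics(left)
    r_path, r_depth, r_area, r_volume = _hand_metrics(right)
    vec = MAPVector(
        l_path=l_path,
        l_depth=l_depth,
        l_area=l_area,
        l_volume=l_volume,
        r_path=r_path,
        r_depth=r_depth,
        r_area=r_area,
        r_volume=r_volume,
        time=max(task_time(left), task_time(right)),
    )
    return TrialMetrics(trial_id=trial_id, group=group, maps=vec)
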