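"""Trocar pivot kinematics for a box-trainer instrument tracker.

A laparoscopic instrument inserted through an instrumented trocar moves in
four degrees of freedom: two tilt rotations about the fixed pivot, insertion
depth along the instrument axis, and axial roll.  This module converts raw
4-DOF tracking samples into 3-D instrument-tip trajectories expressed in a
pivot-centred frame (z-axis pointing out of the box toward the user).

Kinematic convention
--------------------
The two tilts are applied as extrinsic rotations, ``R_x(tilt1)`` followed by
``R_y(tilt2)``, to the reference insertion direction ``(0, 0, -1)``.  This is
the simplest gimbal model consistent with a trocar pivot; the convention is
isolated here so an alternative (e.g. intrinsic order, or a different axis
pairing) can be swapped without touching the metric layer.

Axial roll is carried through the data model but does not move the tip: a
rotation of the instrument about its own axis leaves the tip on that axis.
It is kept (rather than silently dropped) so that file round-trips are
lossless and future grip-orientation metrics can use it.

Angles are degrees in files and public types; radian conversion is internal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TrackingSample",
    "Trajectory",
    "TipPoint",
    "InvalidSampleError",
    "tip_position",
    "to_tip_path",
    "tip_path_array",
    "validate_trajectory",
]

#: Nominal sampling rate of the tracker (Hz).
DEFAULT_SAMPLE_RATE_HZ = 100.0

#: A gap longer than this many sample intervals is flagged as a dropout.
GAP_TOLERANCE_INTERVALS = 3.0


class InvalidSampleError(ValueError):
    """Raised when a tracking sample violates its invariants."""


@dataclass(frozen=True)
class TrackingSample:
    """One 4-DOF measurement of a single instrument.

    Parameters
    ----------
    t : float
        Timestamp in seconds.
    tilt1, tilt2 : float
        Rotations about the two transverse pivot axes, in degrees.
    depth : float
        Insertion distance of the instrument along its own axis past the
        pivot, in millimetres.  Must be non-negative.
    roll : float
        Axial rotation of the instrument about its own axis, in degrees.
        Does not affect tip position.
    """

    t: float
    tilt1: float
    tilt2: float
    depth: float
    roll: float = 0.0

    def validate(self) -> None:
        vals = (self.t, self.tilt1, self.tilt2, self.depth, self.roll)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidSampleError(f"non-finite field in sample {self!r}")
        if self.depth < 0:
            raise InvalidSampleError(f"negative insertion depth {self.depth!r}")


@dataclass(frozen=True)
class TipPoint:
    """Instrument-tip coordinates (mm) in the pivot-centred frame."""

    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Trajectory:
    """An ordered 4-DOF time series for one hand of one trial.

    Invariants (checked on construction): at least one sample, strictly
    increasing timestamps would be ideal but raw logs may contain glitches,
    so ordering problems are reported by :func:`validate_trajectory` rather
    than rejected here; ``fs`` must be positive.
    """

    hand: str
    samples: Sequence[TrackingSample]
    fs: float = DEFAULT_SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        if self.hand not in ("left", "right"):
            raise ValueError(f"hand must be 'left' or 'right', got {self.hand!r}")
        if len(self.samples) < 1:
            raise ValueError("trajectory needs at least one sample")
        if not self.fs > 0:
            raise ValueError(f"sample rate must be positive, got {self.fs!r}")
        self.samples = tuple(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.samples], dtype=float)

    @property
    def depths(self) -> np.ndarray:
        return np.array([s.depth for s in self.samples], dtype=float)

    @property
    def tilts(self) -> np.ndarray:
        """(n, 2) array of the two tilt angles in degrees."""
        return np.array([[s.tilt1, s.tilt2] for s in self.samples], dtype=float)


def _rotation_xy(tilt1_deg: float, tilt2_deg: float) -> np.ndarray:
    """Extrinsic R_y(tilt2) @ R_x(tilt1) as a 3x3 matrix."""
    a = np.deg2rad(tilt1_deg)
    b = np.deg2rad(tilt2_deg)
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    return ry @ rx


def tip_position(sample: TrackingSample) -> TipPoint:
    """Map a 4-DOF sample to the instrument-tip position.

    The tip sits at ``R_y(tilt2) R_x(tilt1) (0, 0, -depth)`` with the pivot
    at the origin.  Roll does not enter: it spins the instrument about the
    very axis the tip lies on.  A depth of zero maps to the origin for any
    tilt angles (the degenerate "tip at the pivot" configuration).
    """
    sample.validate()
    v = _rotation_xy(sample.tilt1, sample.tilt2) @ np.array([0.0, 0.0, -sample.depth])
    return TipPoint(float(v[0]), float(v[1]), float(v[2]))


def to_tip_path(traj: Trajectory) -> list[TipPoint]:
    """Convert a trajectory to its ordered sequence of tip points."""
    return [tip_position(s) for s in traj.samples]


def tip_path_array(traj: Trajectory) -> np.ndarray:
    """Vectorised tip path as an (n, 3) float array.

    Identical to stacking :func:`to_tip_path` but avoids per-sample Python
    overhead on long 100 Hz recordings.
    """
    for s in traj.samples:
        s.validate()
    tilts = np.deg2rad(traj.tilts)
    a, b = tilts[:, 0], tilts[:, 1]
    d = traj.depths
    # R_y(b) R_x(a) @ (0,0,-d), written out componentwise
    x = -d * np.cos(a) * np.sin(b)
    y = d * np.sin(a)
    z = -d * np.cos(a) * np.cos(b)
    return np.column_stack([x, y, z])


def validate_trajectory(traj: Trajectory) -> list[str]:
    """Diagnostic sweep over a trajectory; returns a list of issue strings.

    Reports non-monotone timestamps, sampling gaps longer than
    ``GAP_TOLERANCE_INTERVALS / fs`` seconds, and negative depths.  An empty
    list means the trace is clean.  Never raises.
    """
    issues: list[str] = []
    t = traj.times
    d = traj.depths
    if len(t) > 1:
        dt = np.diff(t)
        bad = np.flatnonzero(dt <= 0)
        for i in bad:
            issues.append(
                f"non-monotone time at sample {i + 1}: "
                f"t={t[i + 1]:.6g} follows t={t[i]:.6g}"
            )
        gap_limit = GAP_TOLERANCE_INTERVALS / traj.fs
        gaps = np.flatnonzero(dt > gap_limit)
        for i in gaps:
            issues.append(
                f"sampling gap of {dt[i]:.4g} s after sample {i} "
                f"(limit {gap_limit:.4g} s at fs={traj.fs:g} Hz)"
            )
    neg = np.flatnonzero(d < 0)
    for i in neg:
        issues.append(f"negative depth {d[i]:.6g} mm at sample {i}")
    nonfinite = np.flatnonzero(
        ~(np.isfinite(t) & np.isfinite(d) & np.isfinite(traj.tilts).all(axis=1))
    )
    for i in nonfinite:
        issues.append(f"non-finite field at sample {i}")
    return issues
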