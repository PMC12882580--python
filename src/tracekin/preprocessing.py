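"""Raw stylus logs -> clean, uniformly sampled trajectories.

Per-trial cleaning rules applied before feature extraction:

* trials with fewer than 2.5 completed traces of the shape are removed;
* trials in which no sample reaches the minimal speed (200 px/s) within the
  5 s grace period are removed;
* the first pi/2 of angular displacement is discounted;
* positional data is resampled with a cubic spline onto a uniform 60 Hz grid.

Angular displacement is measured as the unwrapped polar angle of the stylus
position about the ideal shape's centroid (counter-clockwise positive) —
robust to sample jitter, and computed on the raw samples before trimming.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline

from .shapes import IdealCurve

__all__ = [
    "RawTrajectory",
    "CleanTrajectory",
    "QCRecord",
    "PreprocessConfig",
    "compute_angular_displacement",
    "validate_trial",
    "trim_initial_theta",
    "resample_uniform",
    "preprocess_trial",
]

DROP_REASONS = ("too_few_traces", "too_slow", "timeout", "lifted")


@dataclass
class RawTrajectory:
    """Timestamped stylus samples for one trial attempt."""

    participant: str
    group: str
    day: int
    block: int
    shape: str
    trial: int
    attempt: int
    t: np.ndarray  # s, nondecreasing
    x: np.ndarray  # px
    y: np.ndarray  # px
    success: bool = True

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.t) < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if np.any(np.diff(self.t) < 0):
            raise ValueError("timestamps must be nondecreasing")

    @property
    def meta(self) -> dict:
        return {
            "participant": self.participant,
            "group": self.group,
            "day": self.day,
            "block": self.block,
            "shape": self.shape,
            "trial": self.trial,
            "attempt": self.attempt,
        }


@dataclass
class CleanTrajectory:
    """Uniformly resampled trajectory ready for differentiation."""

    participant: str
    group: str
    day: int
    block: int
    shape: str
    trial: int
    t: np.ndarray  # uniform, 1/rate_hz spacing
    x: np.ndarray
    y: np.ndarray
    theta_traced: np.ndarray  # unwrapped angular displacement, rad
    traces_completed: float
    rate_hz: float = 60.0

    @property
    def meta(self) -> dict:
        return {
            "participant": self.participant,
            "group": self.group,
            "day": self.day,
            "block": self.block,
            "shape": self.shape,
            "trial": self.trial,
        }


@dataclass
class QCRecord:
    """Kept/dropped decision for one trial, with the reason."""

    kept: bool
    reason: Optional[str] = None
    traces_completed: float = np.nan
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PreprocessConfig:
    min_traces: float = 2.5
    min_speed_px_s: float = 200.0
    grace_period_s: float = 5.0
    trim_theta_rad: float = np.pi / 2.0
    rate_hz: float = 60.0
    timeout_s: float = 90.0


def compute_angular_displacement(
    traj: RawTrajectory, curve: IdealCurve
) -> tuple[np.ndarray, float]:
    """Unwrapped polar angle about the ideal curve's centroid.

    The angle is oriented by the shape's own centroid winding so that
    tracing in the task direction always yields increasing theta (the
    petals shape winds clockwise about its centre).  Returns the theta
    series (rad, starting at the raw first-sample angle) and the number of
    completed traces ``(theta_end - theta_start) / 2*pi``.
    """
    if len(traj.t) < 10:
        raise ValueError("need at least 10 samples to count traces")
    cx, cy = curve.centroid
    dx = traj.x - cx
    dy = traj.y - cy
    r = np.hypot(dx, dy)
    if np.all(r < 1e-9):
        raise ValueError("all samples coincide with the shape centroid")
    theta = curve.centroid_winding * np.unwrap(np.arctan2(dy, dx))
    traces = float(theta[-1] - theta[0]) / (2.0 * np.pi)
    return theta, traces


def validate_trial(
    traj: RawTrajectory,
    curve: IdealCurve,
    config: PreprocessConfig = PreprocessConfig(),
) -> QCRecord:
    """Apply the trial-retention rules; never raises, returns reasons."""
    meta = traj.meta
    # acquisition-time flags re-checked from metadata
    if not traj.success:
        return QCRecord(False, "lifted", meta=meta)
    if traj.t[-1] - traj.t[0] > config.timeout_s:
        return QCRecord(False, "timeout", meta=meta)
    try:
        _, traces = compute_angular_displacement(traj, curve)
    except ValueError:
        return QCRecord(False, "too_few_traces", meta=meta)
    if traces < config.min_traces:
        return QCRecord(False, "too_few_traces", traces_completed=traces, meta=meta)
    # minimal speed within the grace period, from raw finite differences
    dt = np.diff(traj.t)
    dt = np.where(dt <= 0, np.nan, dt)
    speed = np.hypot(np.diff(traj.x), np.diff(traj.y)) / dt
    in_grace = traj.t[1:] - traj.t[0] <= config.grace_period_s
    if not np.any(speed[in_grace] >= config.min_speed_px_s):
        return QCRecord(False, "too_slow", traces_completed=traces, meta=meta)
    return QCRecord(True, None, traces_completed=traces, meta=meta)


def trim_initial_theta(
    traj: RawTrajectory,
    theta: np.ndarray,
    trim_rad: float = np.pi / 2.0,
) -> tuple[Optional[RawTrajectory], np.ndarray]:
    """Discount the first ``trim_rad`` of angular displacement.

    Returns the trimmed trajectory and corresponding theta, or ``(None, [])``
    if the span does not exceed the trim (trial dropped as too_few_traces).
    """
    progressed = theta - theta[0]
    keep = progressed >= trim_rad
    if not np.any(keep) or keep.sum() < 4:
        return None, np.empty(0)
    return (
        replace(traj, t=traj.t[keep], x=traj.x[keep], y=traj.y[keep]),
        theta[keep],
    )


def resample_uniform(
    traj: RawTrajectory,
    rate_hz: float = 60.0,
    theta: np.ndarray | None = None,
    traces_completed: float = np.nan,
) -> CleanTrajectory:
    """Cubic-spline resampling of x(t), y(t) onto a uniform grid.

    Duplicate timestamps are collapsed by averaging their positions before
    fitting the (natural) cubic spline; the grid spans [t_first, t_last].
    """
    t, x, y = traj.t, traj.x, traj.y
    th = theta if theta is not None else np.full(len(t), np.nan)
    # collapse duplicate timestamps by averaging
    if np.any(np.diff(t) == 0):
        uniq, inv = np.unique(t, return_inverse=True)
        x = np.bincount(inv, weights=x) / np.bincount(inv)
        y = np.bincount(inv, weights=y) / np.bincount(inv)
        if theta is not None:
            th = np.bincount(inv, weights=th) / np.bincount(inv)
        t = uniq
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps not strictly increasing after de-duplication")
    if len(t) < 4:
        raise ValueError("need at least 4 distinct samples for cubic resampling")
    n = int(np.floor((t[-1] - t[0]) * rate_hz)) + 1
    grid = t[0] + np.arange(n) / rate_hz
    sx = CubicSpline(t, x)
    sy = CubicSpline(t, y)
    if theta is not None:
        th_grid = CubicSpline(t, th)(grid)
    else:
        th_grid = np.full(n, np.nan)
    return CleanTrajectory(
        participant=traj.participant,
        group=traj.group,
        day=traj.day,
        block=traj.block,
        shape=traj.shape,
        trial=traj.trial,
        t=grid,
        x=sx(grid),
        y=sy(grid),
        theta_traced=th_grid,
        traces_completed=traces_completed,
        rate_hz=rate_hz,
    )


def preprocess_trial(
    traj: RawTrajectory,
    curve: IdealCurve,
    config: PreprocessConfig = PreprocessConfig(),
) -> tuple[Optional[CleanTrajectory], QCRecord]:
    """Validate -> trim -> resample; returns (clean | None, QC record)."""
    qc = validate_trial(traj, curve, config)
    if not qc.kept:
        return None, qc
    theta, traces = compute_angular_displacement(traj, curve)
    trimmed, theta_trim = trim_initial_theta(traj, theta, config.trim_theta_rad)
    if trimmed is None:
        return None, QCRecord(False, "too_few_traces", traces_completed=traces, meta=traj.meta)
    clean = resample_uniform(trimmed, config.rate_hz, theta_trim, traces)
    return clean, qc
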