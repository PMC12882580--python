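"""Per-trial kinematic features of a clean tracing trajectory.

Nine features are computed per trial: mean speed, mean |acceleration|, mean
|jerk|, minimum and maximum (log-decile) speed, sub-movement percentage,
speed-curvature gradient (speed modulation, the beta of v ~ kappa^-beta),
spectral arc length (SPARC) smoothness, and mean tracing error.

Derivatives come from a least-squares local-polynomial (Savitzky-Golay)
derivative filter applied stage-wise: position -> velocity -> acceleration ->
jerk.  Edge samples spanning half a filter window per differentiation stage
are excluded from feature aggregation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .preprocessing import CleanTrajectory
from .shapes import IdealCurve, nearest_point_frames

__all__ = [
    "KinematicsConfig",
    "KinematicSeries",
    "SpeedModulationResult",
    "SmoothnessResult",
    "FeatureRecord",
    "differentiate",
    "submovement_percentage",
    "speed_modulation",
    "min_max_speed",
    "sparc",
    "tracing_error",
    "extract_features",
    "FEATURE_NAMES",
]

FEATURE_NAMES = (
    "speed",
    "acceleration",
    "jerk",
    "min_speed",
    "max_speed",
    "submovement_pct",
    "speed_modulation",
    "sparc",
    "error_px",
)


@dataclass(frozen=True)
class KinematicsConfig:
    """Filter and estimator settings (all tunable; defaults documented)."""

    window: int = 11  # Savitzky-Golay window, samples (~183 ms at 60 Hz)
    polyorder: int = 3
    sm_window: int = 11  # smoothing window for the speed-modulation regression
    sm_polyorder: int = 3
    kappa_lo: float = 1e-4  # 1/px, exclusion bounds guarding the log transform
    kappa_hi: float = 1.0
    v_pctile_lo: float = 1.0  # drop speeds below this percentile before the fit
    min_regression_points: int = 50
    sparc_cutoff_hz: float = 20.0
    sparc_amp_threshold: float = 0.05
    sparc_pad_factor: int = 4
    min_element_s: float = 0.25


@dataclass
class KinematicSeries:
    """Derivative stacks for one trial (uniform 60 Hz grid)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    v: np.ndarray  # speed, px/s
    a: np.ndarray  # signed tangential acceleration dv/dt, px/s^2
    j: np.ndarray  # jerk da/dt, px/s^3
    kappa: np.ndarray  # curvature of the traced path, 1/px
    interior: slice  # samples unaffected by filter edges
    theta_traced: np.ndarray | None = None
    rate_hz: float = 60.0


@dataclass
class SpeedModulationResult:
    beta: float  # |slope| of log v on log kappa
    intercept: float
    n_points: int
    r2: float
    reliable: bool


@dataclass
class SmoothnessResult:
    sparc_per_element: list
    sparc: float
    n_elements: int


@dataclass
class FeatureRecord:
    """The nine per-trial dependent variables plus metadata."""

    meta: dict
    speed: float = np.nan
    acceleration: float = np.nan
    jerk: float = np.nan
    min_speed: float = np.nan
    max_speed: float = np.nan
    submovement_pct: float = np.nan
    speed_modulation: float = np.nan
    sparc: float = np.nan
    error_px: float = np.nan
    flags: list = field(default_factory=list)

    def to_row(self) -> dict:
        row = dict(self.meta)
        for name in FEATURE_NAMES:
            row[name] = getattr(self, name)
        return row


def _stagewise_derivative(series: np.ndarray, window: int, polyorder: int, dt: float) -> np.ndarray:
    return savgol_filter(series, window, polyorder, deriv=1, delta=dt)


def differentiate(
    traj: CleanTrajectory, window: int = 11, polyorder: int = 3
) -> KinematicSeries:
    """Stage-wise Savitzky-Golay differentiation of a uniform trajectory.

    Speed is the magnitude of the velocity components; tangential
    acceleration is the (signed) derivative of speed; jerk the derivative of
    tangential acceleration.  Curvature uses the component derivatives:
    kappa = |vx*ay - vy*ax| / v^3.
    """
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    n = len(traj.t)
    if n < window:
        raise ValueError(f"series length {n} shorter than filter window {window}")
    dt = 1.0 / traj.rate_hz
    vx = _stagewise_derivative(traj.x, window, polyorder, dt)
    vy = _stagewise_derivative(traj.y, window, polyorder, dt)
    ax = _stagewise_derivative(vx, window, polyorder, dt)
    ay = _stagewise_derivative(vy, window, polyorder, dt)
    v = np.hypot(vx, vy)
    a = _stagewise_derivative(v, window, polyorder, dt)
    j = _stagewise_derivative(a, window, polyorder, dt)
    v3 = np.maximum(v, 1e-12) ** 3
    kappa = np.abs(vx * ay - vy * ax) / v3
    # three differentiation stages feed the deepest product (jerk)
    edge = 3 * (window // 2)
    interior = slice(edge, n - edge) if n > 2 * edge + 2 else slice(0, n)
    return KinematicSeries(
        t=traj.t, x=traj.x, y=traj.y, vx=vx, vy=vy, v=v, a=a, j=j,
        kappa=kappa, interior=interior, theta_traced=traj.theta_traced,
        rate_hz=traj.rate_hz,
    )


def submovement_percentage(series: KinematicSeries, a_tol_rel: float = 0.002) -> float:
    """Percentage of samples at which tangential acceleration changes sign.

    Zero accelerations inherit the previous sign, so a flat (all-zero)
    profile scores 0%.  Accelerations below ``a_tol_rel * mean speed`` per
    second (default 1 px/s^2 at 500 px/s, several orders below real
    accelerations on this task) are treated as zero so that numerical
    interpolation noise on a constant-speed trace does not register as
    sub-movements.
    """
    a = series.a[series.interior]
    if len(a) < 3:
        raise ValueError("need at least 2 interior samples of acceleration")
    deadband = a_tol_rel * float(np.mean(series.v[series.interior]))
    a = np.where(np.abs(a) < deadband, 0.0, a)
    sign = np.sign(a)
    # zeros inherit the most recent nonzero sign (forward fill)
    nz = sign != 0
    idx = np.maximum.accumulate(np.where(nz, np.arange(len(sign)), -1))
    sign = np.where(idx >= 0, sign[np.maximum(idx, 0)], 0.0)
    changes = np.count_nonzero((sign[1:] != sign[:-1]) & (sign[:-1] != 0))
    return 100.0 * changes / (len(a) - 1)


def speed_modulation(
    series: KinematicSeries, cfg: KinematicsConfig = KinematicsConfig()
) -> SpeedModulationResult:
    """OLS gradient of log speed on log curvature of the traced path.

    Speed and curvature are smoothed with a Savitzky-Golay filter; samples
    with speed below the ``v_pctile_lo`` percentile or curvature outside
    [kappa_lo, kappa_hi] are excluded before the log-log regression.
    """
    idx = series.interior
    v = series.v[idx]
    kappa = series.kappa[idx]
    if len(v) >= cfg.sm_window:
        v = savgol_filter(v, cfg.sm_window, cfg.sm_polyorder)
        kappa = savgol_filter(kappa, cfg.sm_window, cfg.sm_polyorder)
    keep = (
        (v > np.percentile(v, cfg.v_pctile_lo))
        & (kappa >= cfg.kappa_lo)
        & (kappa <= cfg.kappa_hi)
        & (v > 0)
    )
    v, kappa = v[keep], kappa[keep]
    n = len(v)
    reliable = n >= cfg.min_regression_points
    if n < 3:
        return SpeedModulationResult(np.nan, np.nan, n, np.nan, False)
    logv = np.log(v)
    logk = np.log(kappa)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        slope, intercept = np.polyfit(logk, logv, 1)
    pred = slope * logk + intercept
    ss_res = float(np.sum((logv - pred) ** 2))
    ss_tot = float(np.sum((logv - logv.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return SpeedModulationResult(abs(float(slope)), float(intercept), n, r2, reliable)


def min_max_speed(series: KinematicSeries) -> tuple[float, float]:
    """Mean of the bottom and top deciles of log speed (decile = ceil(N/10))."""
    v = series.v[series.interior]
    v = v[v > 0]
    if len(v) < 10:
        raise ValueError("need at least 10 positive-speed samples")
    logv = np.sort(np.log(v))
    k = int(np.ceil(0.1 * len(logv)))
    return float(logv[:k].mean()), float(logv[-k:].mean())


def _sparc_single(
    v: np.ndarray,
    rate_hz: float,
    cutoff_hz: float,
    amp_threshold: float,
    pad_factor: int,
) -> float:
    """Spectral arc length of one speed profile (standard formulation).

    Magnitude spectrum of the zero-padded speed profile, normalised by its
    DC value, truncated at an adaptive cutoff no higher than ``cutoff_hz``
    (the last frequency at which the normalised magnitude still exceeds
    ``amp_threshold``); returns the negative arc length of the normalised
    spectrum against normalised frequency.
    """
    n = len(v)
    nfft = int(2 ** np.ceil(np.log2(n * max(pad_factor, 1))))
    mag = np.abs(np.fft.rfft(v, nfft))
    freq = np.fft.rfftfreq(nfft, d=1.0 / rate_hz)
    mag = mag / mag[0]
    in_band = freq <= cutoff_hz
    freq_b, mag_b = freq[in_band], mag[in_band]
    above = np.nonzero(mag_b >= amp_threshold)[0]
    i_cut = above[-1] if len(above) else len(mag_b) - 1
    i_cut = max(i_cut, 1)
    freq_c = freq_b[: i_cut + 1]
    mag_c = mag_b[: i_cut + 1]
    df = np.diff(freq_c / freq_c[-1])
    dm = np.diff(mag_c)
    return -float(np.sum(np.sqrt(df**2 + dm**2)))


def _element_boundaries(curve: IdealCurve) -> np.ndarray:
    """Oriented polar angles (about the centroid) of the ideal curvature
    maxima, wrapped to (-pi, pi].

    Splitting a trace where its oriented angular displacement crosses these
    angles yields one sub-element per curvature oscillation — p identical
    elements per completed trace of the shape.
    """
    kappa = curve.kappa
    idx = np.nonzero((kappa[1:-1] > kappa[:-2]) & (kappa[1:-1] > kappa[2:]))[0] + 1
    cx, cy = curve.centroid
    phi = curve.centroid_winding * np.arctan2(curve.y[idx] - cy, curve.x[idx] - cx)
    return np.unique(np.round(np.sort(phi), 9))


def sparc(
    series: KinematicSeries,
    curve: IdealCurve,
    cfg: KinematicsConfig = KinematicsConfig(),
) -> SmoothnessResult:
    """Mean spectral arc length over repeated identical shape sub-elements.

    The trial is split where the traced angular displacement crosses the
    polar angles of the ideal curve's curvature maxima (one element per
    curvature oscillation); each element's speed profile is scored
    separately and the per-element values averaged.  Elements shorter than
    ``min_element_s`` are skipped.
    """
    if series.theta_traced is None or np.all(np.isnan(series.theta_traced)):
        raise ValueError("traced angular displacement required for sub-elements")
    theta = series.theta_traced[series.interior]
    v = series.v[series.interior]
    bounds = _element_boundaries(curve)
    if len(bounds) == 0:
        raise ValueError("ideal curve has no curvature maxima")
    winding = 2.0 * np.pi  # oriented polar-angle span of one completed trace
    # absolute boundary angles across all completed cycles of the trace
    lo, hi = theta.min(), theta.max()
    k_lo = int(np.floor((lo - bounds.max()) / winding)) - 1
    k_hi = int(np.ceil((hi - bounds.min()) / winding)) + 1
    all_bounds = np.sort(
        np.concatenate([bounds + k * winding for k in range(k_lo, k_hi + 1)])
    )
    all_bounds = all_bounds[(all_bounds > lo) & (all_bounds < hi)]
    # first index at which the trace's running-max angle passes each boundary
    # (robust to small local backtracks of the traced angle)
    cut_idx = np.searchsorted(np.maximum.accumulate(theta), all_bounds)
    segments = np.split(np.arange(len(v)), np.unique(cut_idx))
    # interior elements only: first and last are partial oscillations
    segments = segments[1:-1] if len(segments) > 2 else segments
    min_len = int(cfg.min_element_s * series.rate_hz)
    values = [
        _sparc_single(v[seg], series.rate_hz, cfg.sparc_cutoff_hz,
                      cfg.sparc_amp_threshold, cfg.sparc_pad_factor)
        for seg in segments
        if len(seg) >= min_len
    ]
    if not values:
        raise ValueError("no sub-element long enough to score")
    return SmoothnessResult(values, float(np.mean(values)), len(values))


def tracing_error(
    traj_or_series, curve: IdealCurve, interior: slice | None = None
) -> float:
    """Mean |normal distance to the tangent at the nearest ideal point|, px."""
    x = traj_or_series.x
    y = traj_or_series.y
    if interior is None and isinstance(traj_or_series, KinematicSeries):
        interior = traj_or_series.interior
    if interior is not None:
        x, y = x[interior], y[interior]
    _, _, dist = nearest_point_frames(curve, np.column_stack([x, y]))
    return float(np.mean(np.abs(dist)))


def extract_features(
    traj: CleanTrajectory,
    curve: IdealCurve,
    cfg: KinematicsConfig = KinematicsConfig(),
) -> FeatureRecord:
    """Compose the nine per-trial dependent variables.

    Any sub-computation that fails or is flagged unreliable leaves its
    feature missing (NaN) with a note in ``flags``.
    """
    rec = FeatureRecord(meta=traj.meta)
    try:
        series = differentiate(traj, cfg.window, cfg.polyorder)
    except ValueError as exc:
        rec.flags.append(f"differentiate: {exc}")
        return rec
    idx = series.interior
    rec.speed = float(np.mean(series.v[idx]))
    rec.acceleration = float(np.mean(np.abs(series.a[idx])))
    rec.jerk = float(np.mean(np.abs(series.j[idx])))
    try:
        rec.min_speed, rec.max_speed = min_max_speed(series)
    except ValueError as exc:
        rec.flags.append(f"min_max_speed: {exc}")
    try:
        rec.submovement_pct = submovement_percentage(series)
    except ValueError as exc:
        rec.flags.append(f"submovement: {exc}")
    sm = speed_modulation(series, cfg)
    if sm.reliable:
        rec.speed_modulation = sm.beta
    else:
        rec.flags.append(f"speed_modulation unreliable (n={sm.n_points})")
    try:
        rec.sparc = sparc(series, curve, cfg).sparc
    except ValueError as exc:
        rec.flags.append(f"sparc: {exc}")
    rec.error_px = tracing_error(series, curve)
    return rec
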