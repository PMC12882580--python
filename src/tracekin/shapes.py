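"""Pure-frequency target shapes for the tracing task.

The four task shapes (clover, petals, ellipse, rounded square) belong to the
family of *pure frequency* curves: closed convex-curvature curves whose
log-curvature varies sinusoidally with angular displacement,

    kappa(theta) = kappa0 * exp(epsilon * sin(nu * theta)),

where ``theta`` is the tangent heading (angular displacement, radians) and
``nu = p/q`` is the angular frequency — the number of curvature oscillations
per 2*pi of angular displacement.  Integrating

    dx/dtheta = cos(theta) / kappa(theta),
    dy/dtheta = sin(theta) / kappa(theta)

over theta in [0, 2*pi*q] yields a closed curve whenever p does not divide q
(the Fourier modes of 1/kappa never hit frequency 1), which holds for all
four task shapes: nu = 4/5, 4/3, 2/1 and 4/1.

Curves are expressed in pixels with the origin at the bottom left and y
increasing upward; positive theta is counter-clockwise traversal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import gcd
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

__all__ = [
    "ShapeSpec",
    "IdealCurve",
    "SHAPE_LIBRARY",
    "shape_spec",
    "generate_pure_frequency_shape",
    "count_curvature_oscillations",
    "nearest_point_frame",
    "curve_to_frame",
    "curve_from_frame",
    "all_task_shapes",
    "nearest_point_frames",
    "DEVICE_PX_PER_MM",
    "DEFAULT_MAX_DIM_PX",
]

# Samsung Galaxy Tab A7: 2000 x 1200 px on a 10.40-inch diagonal.
DEVICE_PX_PER_MM = np.hypot(2000.0, 1200.0) / (10.40 * 25.4)
# Shapes are scaled so neither bounding-box dimension exceeds 9 cm.
DEFAULT_MAX_DIM_PX = 90.0 * DEVICE_PX_PER_MM

#: name -> (p, q, default log-curvature oscillation amplitude epsilon)
SHAPE_LIBRARY: dict[str, tuple[int, int, float]] = {
    "clover": (4, 5, 1.2),
    "petals": (4, 3, 1.0),
    "ellipse": (2, 1, 0.7),
    "rounded_square": (4, 1, 0.8),
}

SHAPE_NAMES = tuple(SHAPE_LIBRARY)


@dataclass(frozen=True)
class ShapeSpec:
    """Parameters of one pure-frequency target shape.

    Attributes
    ----------
    name : str
        Shape label; the four named task shapes live in :data:`SHAPE_LIBRARY`.
    p, q : int
        Angular frequency ``nu = p/q`` in lowest terms (curvature
        oscillations per 2*pi of angular displacement).
    epsilon : float
        Dimensionless amplitude of the log-curvature oscillation.  Must be
        positive; for the amplitudes used here the curvature never changes
        sign, so the curves are inflection-free.
    max_dim_px : float
        The larger bounding-box dimension of the rendered curve, pixels.
    samples_per_cycle : int
        Integration / sampling density per 2*pi of angular displacement.
    """

    name: str
    p: int
    q: int
    epsilon: float
    max_dim_px: float = DEFAULT_MAX_DIM_PX
    samples_per_cycle: int = 2048

    def __post_init__(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ValueError("angular frequency p/q must be positive")
        if gcd(self.p, self.q) != 1:
            raise ValueError(f"p/q = {self.p}/{self.q} is not in lowest terms")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be > 0")
        if not self.max_dim_px > 0:
            raise ValueError("max_dim_px must be > 0")
        if self.samples_per_cycle < 256:
            raise ValueError("samples_per_cycle must be >= 256")

    @property
    def nu(self) -> float:
        return self.p / self.q

    @property
    def theta_span(self) -> float:
        """Angular displacement of one full closed traversal."""
        return 2.0 * np.pi * self.q


def shape_spec(name: str, **overrides) -> ShapeSpec:
    """Look up a named task shape, optionally overriding defaults."""
    try:
        p, q, epsilon = SHAPE_LIBRARY[name]
    except KeyError:
        raise KeyError(
            f"unknown shape {name!r}; expected one of {sorted(SHAPE_LIBRARY)}"
        ) from None
    params = dict(name=name, p=p, q=q, epsilon=epsilon)
    params.update(overrides)
    return ShapeSpec(**params)


class CurveClosureError(RuntimeError):
    """The integrated curve failed to close within tolerance."""


@dataclass
class IdealCurve:
    """Arc-length parameterised target shape.

    Arrays are sampled on a uniform theta grid over one closed traversal,
    ``theta in [0, 2*pi*q]`` inclusive (first and last points coincide).
    """

    theta: np.ndarray  # angular displacement, rad, strictly increasing
    s: np.ndarray  # cumulative arc length, px
    x: np.ndarray  # px
    y: np.ndarray  # px
    kappa: np.ndarray  # curvature, 1/px, > 0
    closed: bool
    spec: ShapeSpec
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)
    _splines: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def perimeter(self) -> float:
        return float(self.s[-1])

    @property
    def centroid(self) -> np.ndarray:
        # drop the duplicated closing point so it is not double-weighted
        return np.array([self.x[:-1].mean(), self.y[:-1].mean()])

    @property
    def bbox(self) -> tuple[float, float]:
        """(width, height) of the bounding box, px."""
        return (float(np.ptp(self.x)), float(np.ptp(self.y)))

    def position_at_s(self, s_query: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Periodic cubic-spline position at arc lengths (wraps modulo perimeter)."""
        if self._splines is None:
            self._splines = (
                CubicSpline(self.s, self.x, bc_type="periodic"),
                CubicSpline(self.s, self.y, bc_type="periodic"),
            )
        sx, sy = self._splines
        sq = np.mod(s_query, self.perimeter)
        return sx(sq), sy(sq)

    def kappa_at_s(self, s_query: np.ndarray) -> np.ndarray:
        sq = np.mod(s_query, self.perimeter)
        return np.interp(sq, self.s, self.kappa)

    def theta_at_s(self, s_query: np.ndarray) -> np.ndarray:
        """Unwrapped heading at (possibly multi-cycle) arc length."""
        s_query = np.asarray(s_query, dtype=float)
        cycles = np.floor_divide(s_query, self.perimeter)
        sq = np.mod(s_query, self.perimeter)
        return np.interp(sq, self.s, self.theta) + cycles * self.spec.theta_span

    @property
    def centroid_winding(self) -> int:
        """Signed winding of the position about the centroid per traversal.

        Counter-clockwise heading does not imply counter-clockwise position
        winding: the petals shape (nu = 4/3) winds clockwise about its
        centre while its tangent turns counter-clockwise.  Trace counting
        and sub-element splitting orient angles by this sign.
        """
        cx, cy = self.centroid
        phi = np.unwrap(np.arctan2(self.y - cy, self.x - cx))
        w = (phi[-1] - phi[0]) / (2.0 * np.pi)
        return int(np.sign(np.round(w))) or 1

    def kdtree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(np.column_stack([self.x, self.y]))
        return self._tree


def _kappa_unit(theta: np.ndarray | float, spec: ShapeSpec) -> np.ndarray:
    """Curvature of the unit (kappa0 = 1, unscaled) curve."""
    return np.exp(spec.epsilon * np.sin(spec.nu * np.asarray(theta, dtype=float)))


def generate_pure_frequency_shape(spec: ShapeSpec) -> IdealCurve:
    """Integrate and scale one pure-frequency curve.

    Position is obtained from the heading ODE with fixed-step RK4 at
    ``samples_per_cycle`` steps per 2*pi; a residual translation drift (RK4
    truncation error — the curve closes analytically) is removed linearly in
    theta, then the curve is uniformly scaled so its larger bounding-box
    dimension equals ``max_dim_px``.

    Raises
    ------
    CurveClosureError
        If the endpoint gap exceeds 1e-6 of the perimeter after correction.
    """
    n = spec.samples_per_cycle * spec.q
    theta = np.linspace(0.0, spec.theta_span, n + 1)
    h = theta[1] - theta[0]

    def rhs(th: float) -> np.ndarray:
        inv_k = 1.0 / _kappa_unit(th, spec)
        return np.array([np.cos(th) * inv_k, np.sin(th) * inv_k])

    # RK4 on a state that also accumulates arc length ds/dtheta = 1/kappa.
    xy = np.empty((n + 1, 2))
    s = np.empty(n + 1)
    xy[0] = 0.0
    s[0] = 0.0
    state = np.zeros(3)
    for i in range(n):
        th = theta[i]

        def f(th_: float) -> np.ndarray:
            inv_k = 1.0 / float(_kappa_unit(th_, spec))
            return np.array([np.cos(th_) * inv_k, np.sin(th_) * inv_k, inv_k])

        k1 = f(th)
        k2 = f(th + 0.5 * h)
        k3 = f(th + 0.5 * h)
        k4 = f(th + h)
        state = state + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        xy[i + 1] = state[:2]
        s[i + 1] = state[2]

    # closure correction: remove integration drift linearly in theta
    gap = xy[-1] - xy[0]
    frac = (theta - theta[0]) / (theta[-1] - theta[0])
    xy = xy - gap[None, :] * frac[:, None]

    residual = float(np.hypot(*(xy[-1] - xy[0])))
    if residual > 1e-6 * s[-1]:
        raise CurveClosureError(
            f"curve {spec.name!r} failed to close: residual gap {residual:.3g} px"
        )
    xy[-1] = xy[0]

    # uniform scale so the larger bounding-box dimension hits max_dim_px
    width = np.ptp(xy[:, 0])
    height = np.ptp(xy[:, 1])
    scale = spec.max_dim_px / max(width, height)
    xy = xy * scale
    s = s * scale
    kappa = _kappa_unit(theta, spec) / scale

    # origin at bottom-left of the bounding box
    xy = xy - xy.min(axis=0)

    return IdealCurve(
        theta=theta,
        s=s,
        x=xy[:, 0],
        y=xy[:, 1],
        kappa=kappa,
        closed=True,
        spec=spec,
    )


class DegenerateCurveError(ValueError):
    """Oscillation count is undefined (open or constant-curvature curve)."""


def count_curvature_oscillations(
    curve_or_kappa, theta: np.ndarray | None = None, rel_tol: float = 1e-9
) -> float:
    """Strict local curvature maxima per 2*pi of angular displacement.

    Accepts an :class:`IdealCurve` or a (kappa, theta) pair.  The count is
    normalised by the theta span: a full closed traversal (span ``2*pi*q``)
    of a shape with angular frequency p/q returns exactly p/q... times 2*pi,
    i.e. p * 2*pi / (2*pi*q) = p/q per 2*pi.
    """
    if theta is None:
        kappa = curve_or_kappa.kappa
        theta = curve_or_kappa.theta
    else:
        kappa = np.asarray(curve_or_kappa, dtype=float)
    if len(kappa) < 3:
        raise DegenerateCurveError("need at least 3 samples")
    span = float(theta[-1] - theta[0])
    if span <= 0:
        raise DegenerateCurveError("theta span must be positive")
    if np.ptp(kappa) <= rel_tol * np.abs(kappa).max():
        raise DegenerateCurveError("constant-curvature curve has no oscillations")
    interior = (kappa[1:-1] > kappa[:-2]) & (kappa[1:-1] > kappa[2:])
    n_max = int(np.count_nonzero(interior))
    if n_max == 0:
        raise DegenerateCurveError("no strict local curvature maxima found")
    return n_max * 2.0 * np.pi / span


def nearest_point_frame(
    curve: IdealCurve, point: tuple[float, float] | np.ndarray
) -> tuple[float, np.ndarray, float]:
    """Nearest-point frame of a query point on the curve polyline.

    Returns ``(s, tangent, normal_distance)``: the arc length of the nearest
    point (polyline nearest vertex refined over its adjacent segments, ties
    broken by smallest s), the unit tangent there, and the signed
    perpendicular offset of the point from the tangent line (positive to the
    left of the tangent, i.e. outward for counter-clockwise traversal of a
    convex region is negative).
    """
    s, tangent, dist = nearest_point_frames(curve, np.atleast_2d(np.asarray(point, float)))
    return float(s[0]), tangent[0], float(dist[0])


def nearest_point_frames(
    curve: IdealCurve, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised :func:`nearest_point_frame` over an (n, 2) point array."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must have shape (n, 2)")
    if len(curve.x) == 0:
        raise ValueError("empty curve")

    verts = np.column_stack([curve.x, curve.y])
    n_seg = len(verts) - 1  # closing point duplicates the first
    _, idx = curve.kdtree().query(points)

    best_d2 = np.full(len(points), np.inf)
    best_s = np.zeros(len(points))
    best_seg = np.zeros(len(points), dtype=int)
    best_u = np.zeros(len(points))

    # candidate segments around the nearest vertex (wrap for closed curves)
    for off in (-1, 0):
        seg = (idx + off) % n_seg if curve.closed else np.clip(idx + off, 0, n_seg - 1)
        a = verts[seg]
        b = verts[seg + 1]
        ab = b - a
        denom = np.einsum("ij,ij->i", ab, ab)
        denom = np.where(denom == 0.0, 1.0, denom)
        u = np.clip(np.einsum("ij,ij->i", points - a, ab) / denom, 0.0, 1.0)
        foot = a + u[:, None] * ab
        d2 = np.einsum("ij,ij->i", points - foot, points - foot)
        s_cand = curve.s[seg] + u * (curve.s[seg + 1] - curve.s[seg])
        better = d2 < best_d2 - 1e-12
        tie = np.abs(d2 - best_d2) <= 1e-12
        take = better | (tie & (s_cand < best_s))
        best_d2 = np.where(take, d2, best_d2)
        best_s = np.where(take, s_cand, best_s)
        best_seg = np.where(take, seg, best_seg)
        best_u = np.where(take, u, best_u)

    # tangent from the heading theta, interpolated within the segment
    th = curve.theta[best_seg] + best_u * (
        curve.theta[best_seg + 1] - curve.theta[best_seg]
    )
    tangent = np.column_stack([np.cos(th), np.sin(th)])
    foot_x, foot_y = (
        curve.x[best_seg] + best_u * (curve.x[best_seg + 1] - curve.x[best_seg]),
        curve.y[best_seg] + best_u * (curve.y[best_seg + 1] - curve.y[best_seg]),
    )
    rel = points - np.column_stack([foot_x, foot_y])
    # signed perpendicular offset from the tangent line
    normal_dist = tangent[:, 0] * rel[:, 1] - tangent[:, 1] * rel[:, 0]
    return best_s, tangent, normal_dist


def curve_to_frame(curve: IdealCurve) -> pd.DataFrame:
    """Tabular export (columns theta, s, x, y, kappa) with spec attrs."""
    df = pd.DataFrame(
        {
            "theta": curve.theta,
            "s": curve.s,
            "x": curve.x,
            "y": curve.y,
            "kappa": curve.kappa,
        }
    )
    df.attrs["spec"] = {
        "name": curve.spec.name,
        "p": curve.spec.p,
        "q": curve.spec.q,
        "epsilon": curve.spec.epsilon,
        "max_dim_px": curve.spec.max_dim_px,
    }
    return df


def curve_from_frame(df: pd.DataFrame, spec: ShapeSpec) -> IdealCurve:
    return IdealCurve(
        theta=df["theta"].to_numpy(),
        s=df["s"].to_numpy(),
        x=df["x"].to_numpy(),
        y=df["y"].to_numpy(),
        kappa=df["kappa"].to_numpy(),
        closed=True,
        spec=spec,
    )


def all_task_shapes(
    names: Iterable[str] = SHAPE_NAMES, **overrides
) -> dict[str, IdealCurve]:
    """Generate the named task shapes once (they are deterministic)."""
    return {name: generate_pure_frequency_shape(shape_spec(name, **overrides)) for name in names}
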