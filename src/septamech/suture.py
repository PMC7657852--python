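"""Suture-line generation.

A septum meets the shell wall along a closed curve, the suture line.  Two
families are generated here:

* *lobate* curves -- smooth periodic curves with ``n`` primary lobes, built
  from a short cosine series.  They stand in for the primary suture lines of
  early ammonoids (trilobate through sexilobate).
* *Koch* curves -- fractal curves built by repeated application of a
  four-segment generator, modelling the higher-order frilling (first to third
  order folds) of ammonitic sutures.  The generated half-wave is duplicated
  ``n_copies`` times around the circumference.

Planar curves live on the unit arc-position interval ``x in [0, 1]`` with an
axial coordinate ``y`` in mm; :func:`wrap_on_cylinder` maps them onto a
cylinder of given radius, producing the closed 3-D boundary curve used as the
boundary condition of the minimum-curvature septal surface.

Coordinate convention: the cylinder axis is z, theta is measured
counter-clockwise from +x, all lengths are in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import GeometryError, ParameterError

__all__ = [
    "PlanarCurve",
    "SutureCurve",
    "SutureSpec",
    "koch_curve",
    "lobate_curve",
    "wrap_on_cylinder",
    "max_safe_offset",
    "polyline_self_intersects",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class PlanarCurve:
    """A planar suture profile ``y(x)`` with arc position ``x`` in [0, 1].

    ``x`` is strictly increasing; if ``periodic`` the first and last points
    represent the same material point (``x=0`` and ``x=1``) and must carry the
    same ``y``.
    """

    x: np.ndarray
    y: np.ndarray
    periodic: bool = True

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise ParameterError("x and y must be 1-D arrays of equal length")
        if self.x.size < 2:
            raise ParameterError("a curve needs at least two points")
        dx = np.diff(self.x)
        if np.any(dx <= 0):
            raise GeometryError("arc positions must be strictly increasing")
        if self.periodic and abs(self.y[0] - self.y[-1]) > 1e-9 * max(
            1.0, np.ptp(self.y)
        ):
            raise GeometryError("periodic curve endpoints do not join")

    @property
    def n_segments(self) -> int:
        return self.x.size - 1

    @property
    def amplitude(self) -> float:
        """Peak-to-peak axial extent in mm."""
        return float(np.ptp(self.y))

    def interp(self, x: np.ndarray) -> np.ndarray:
        """Piecewise-linear evaluation of y at arc positions (periodic)."""
        xq = np.mod(x, 1.0) if self.periodic else np.asarray(x, float)
        return np.interp(xq, self.x, self.y)

    def centred(self) -> "PlanarCurve":
        """Return a copy with the axial midrange shifted to zero."""
        if self.amplitude == 0.0:
            return PlanarCurve(self.x.copy(), np.zeros_like(self.y), self.periodic)
        mid = 0.5 * (self.y.max() + self.y.min())
        return PlanarCurve(self.x.copy(), self.y - mid, self.periodic)


@dataclass
class SutureCurve:
    """Closed 3-D suture curve lying on a cylinder.

    ``points`` includes the repeated closing point (first == last).  The
    originating planar profile is kept so the axial position ``z(theta)`` can
    be evaluated exactly as the piecewise-linear curve geometry.
    """

    points: np.ndarray
    cylinder_radius: float
    axial_center: float = 0.0
    closed: bool = True
    planar: PlanarCurve | None = field(default=None, repr=False)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ParameterError("points must be an (N, 3) array")
        r = np.hypot(self.points[:, 0], self.points[:, 1])
        if np.any(np.abs(r - self.cylinder_radius) > 1e-6):
            raise GeometryError("suture points do not lie on the cylinder")
        if self.closed and not np.allclose(
            self.points[0], self.points[-1], atol=1e-9
        ):
            raise GeometryError("closed curve must repeat its first point")

    def z_of_theta(self, theta: np.ndarray) -> np.ndarray:
        """Axial position of the suture at angle theta (radians)."""
        if self.planar is None:
            raise GeometryError("suture has no planar profile attached")
        x = np.asarray(theta, float) / (2.0 * np.pi)
        return self.axial_center + self.planar.interp(x)

    def unrolled(self) -> np.ndarray:
        """Curve developed onto the (arc length, z) plane, shape (N, 2)."""
        theta = np.unwrap(np.arctan2(self.points[:, 1], self.points[:, 0]))
        s = theta * self.cylinder_radius
        s = s - s[0]
        return np.column_stack([s, self.points[:, 2]])

    @property
    def arc_length(self) -> float:
        d = np.diff(self.points, axis=0)
        return float(np.sqrt((d**2).sum(axis=1)).sum())

    def is_simple(self) -> bool:
        """Brute-force self-intersection test on the unrolled cylinder."""
        u = self.unrolled()[:-1]
        return not _periodic_self_intersects(u, 2.0 * np.pi * self.cylinder_radius)


@dataclass
class SutureSpec:
    """Parametric description of a suture family member."""

    family: str = "lobate"  # "lobate" | "koch"
    n_lobes: int = 6
    iterations: int = 1
    n_copies: int = 4
    amplitude: float | None = None  # mm peak-to-peak; None -> 0.2 * radius
    koch_angle: float = 25.0  # generator bump angle, degrees
    lobate_weights: tuple[float, ...] = (1.0, 0.18, 0.03)

    def __post_init__(self):
        if self.family not in ("lobate", "koch"):
            raise ParameterError(f"unknown suture family {self.family!r}")
        if self.n_lobes < 1:
            raise ParameterError("n_lobes must be >= 1")
        if self.iterations < 0:
            raise ParameterError("iterations must be >= 0")
        if self.amplitude is not None and self.amplitude <= 0:
            raise ParameterError("amplitude must be positive")

    def resolve_amplitude(self, radius: float) -> float:
        return self.amplitude if self.amplitude is not None else 0.2 * radius

    def make_planar(self, radius: float) -> PlanarCurve:
        amp = self.resolve_amplitude(radius)
        if self.family == "koch":
            return koch_curve(
                self.iterations,
                n_copies=self.n_copies,
                amplitude=amp,
                angle=self.koch_angle,
            )
        return lobate_curve(self.n_lobes, amp, weights=self.lobate_weights)

    @property
    def n_primary(self) -> int:
        """Number of primary lobes (= mirror-symmetry half-order)."""
        return self.n_copies if self.family == "koch" else self.n_lobes

    def label(self) -> str:
        if self.family == "koch":
            return f"koch{self.iterations}"
        names = {3: "trilobate", 4: "quadrilobate", 5: "quinquelobate", 6: "sexilobate"}
        return names.get(self.n_lobes, f"lobate{self.n_lobes}")


# --------------------------------------------------------------------------
# curve generators
# --------------------------------------------------------------------------

def _koch_vertices(iterations: int, angle_rad: float) -> np.ndarray:
    """Vertices of one generator copy on [0, 1], via repeated substitution.

    Four-segment generator: the middle third of every segment is replaced by a
    symmetric triangular bump whose flank makes ``angle_rad`` with the
    baseline.  ``angle_rad = 60 deg`` gives the classic triadic Koch curve;
    smaller angles keep the curve a single-valued graph y(x) at higher
    iterations, which the conformal shell meshing requires.
    """
    pts = np.array([[0.0, 0.0], [1.0, 0.0]])
    h_rel = np.tan(angle_rad) / 6.0  # bump apex height per unit segment length
    for _ in range(iterations):
        p, q = pts[:-1], pts[1:]
        d = q - p
        n = np.column_stack([-d[:, 1], d[:, 0]])  # left normal * |d|
        a = p + d / 3.0
        b = p + 2.0 * d / 3.0
        apex = p + 0.5 * d + h_rel * n
        new = np.empty((p.shape[0], 4, 2))
        new[:, 0] = p
        new[:, 1] = a
        new[:, 2] = apex
        new[:, 3] = b
        pts = np.vstack([new.reshape(-1, 2), pts[-1:]])
    return pts


def koch_curve(
    iterations: int,
    n_copies: int = 4,
    amplitude: float = 1.0,
    smooth: bool = True,
    angle: float = 25.0,
    samples_per_segment: int = 4,
) -> PlanarCurve:
    """Generate a (optionally spline-smoothed) Koch suture profile.

    Parameters
    ----------
    iterations:
        Number of generator applications per copy; segment count per copy is
        ``4**iterations`` before smoothing.
    n_copies:
        How many copies tile the circumference (four primary lobes by
        default).
    amplitude:
        Peak-to-peak axial extent in mm of the final (smoothed) curve.
    smooth:
        If true, pass a periodic cubic spline through the generator vertices
        and sample it densely; the polygonal vertices are returned otherwise.
    angle:
        Bump angle of the generator in degrees (60 is the classic Koch
        snowflake generator; the default 25 keeps three iterations free of
        x-overhangs so the curve remains a height field over arc position).
    """
    if iterations < 0:
        raise ParameterError("iterations must be >= 0")
    if not 0 <= iterations <= 6:
        raise ParameterError("iterations outside supported range 0..6")
    if n_copies < 1:
        raise ParameterError("n_copies must be >= 1")
    if amplitude < 0:
        raise ParameterError("amplitude must be non-negative")

    copy = _koch_vertices(iterations, np.deg2rad(angle))
    parts = []
    for k in range(n_copies):
        seg = copy.copy()
        seg[:, 0] = (seg[:, 0] + k) / n_copies
        parts.append(seg if k == n_copies - 1 else seg[:-1])
    verts = np.vstack(parts)

    x, y = verts[:, 0], verts[:, 1]
    if smooth and iterations > 0:
        # periodic spline through the generator vertices, same topology
        spl = CubicSpline(x, y, bc_type="periodic")
        n_out = verts.shape[0] * samples_per_segment
        xs = np.linspace(0.0, 1.0, n_out + 1)
        ys = spl(np.clip(xs, x[0], x[-1]))
        x, y = xs, ys
    ptp = np.ptp(y)
    if ptp > 0 and amplitude > 0:
        y = y * (amplitude / ptp)
    y = y - 0.5 * (y.max() + y.min())
    return PlanarCurve(x, y, periodic=True)


def lobate_curve(
    n_lobes: int,
    amplitude: float,
    weights: tuple[float, ...] = (1.0, 0.18, 0.03),
    samples_per_lobe: int = 64,
) -> PlanarCurve:
    """Smooth periodic suture profile with exactly ``n_lobes`` primary lobes.

    The curve is a short cosine series ``y(x) = -sum_k w_k cos(2 pi k n x)``
    rescaled to the requested peak-to-peak amplitude.  It is bilaterally
    symmetric about every lobe and saddle axis; the default weights produce
    lobes slightly narrower than the saddles, as in primary ammonoid sutures.
    Lobes (local minima) point toward negative y.
    """
    if n_lobes < 1:
        raise ParameterError("n_lobes must be >= 1")
    if amplitude <= 0:
        raise ParameterError("amplitude must be positive")
    n_pts = n_lobes * samples_per_lobe
    x = np.linspace(0.0, 1.0, n_pts + 1)
    y = np.zeros_like(x)
    for k, w in enumerate(weights, start=1):
        y -= w * np.cos(2.0 * np.pi * k * n_lobes * x)
    y *= amplitude / np.ptp(y)
    y -= 0.5 * (y.max() + y.min())
    curve = PlanarCurve(x, y, periodic=True)
    if count_local_minima(curve) != n_lobes:
        raise ParameterError(
            "lobate weights do not produce exactly n_lobes minima per period"
        )
    return curve


def count_local_minima(curve: PlanarCurve) -> int:
    """Count local minima per period via sign changes of the discrete slope."""
    y = curve.y[:-1] if curve.periodic else curve.y
    dy = np.diff(np.concatenate([y, y[:1]])) if curve.periodic else np.diff(y)
    s = np.sign(dy)
    s = s[s != 0]
    if s.size == 0:
        return 0
    return int(np.sum((s[:-1] < 0) & (s[1:] > 0)) + ((s[-1] < 0) & (s[0] > 0)))


# --------------------------------------------------------------------------
# wrapping and offsets
# --------------------------------------------------------------------------

def wrap_on_cylinder(
    curve: PlanarCurve, radius: float, axial_center: float = 0.0
) -> SutureCurve:
    """Wrap a periodic planar profile onto a cylinder of given radius.

    Arc position maps to angle, ``theta = 2 pi x``; the result is the closed
    suture curve ``(r cos theta, r sin theta, axial_center + y)``.
    """
    if radius <= 0:
        raise ParameterError("radius must be positive")
    if not curve.periodic:
        raise GeometryError("only periodic curves can be wrapped into a closed suture")
    if abs(curve.y[0] - curve.y[-1]) > 1e-9 * max(1.0, curve.amplitude):
        raise GeometryError("curve endpoints do not join")
    c = curve.centred()
    theta = 2.0 * np.pi * c.x
    pts = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), axial_center + c.y]
    )
    pts[-1] = pts[0]  # exact closure
    return SutureCurve(
        points=pts,
        cylinder_radius=radius,
        axial_center=axial_center,
        closed=True,
        planar=c,
    )


def _segments_intersect(p1, p2, q1, q2) -> np.ndarray:
    """Vectorised proper-intersection test for segment arrays."""
    d1 = p2 - p1
    d2 = q2 - q1
    denom = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    dp = q1 - p1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (dp[:, 0] * d2[:, 1] - dp[:, 1] * d2[:, 0]) / denom
        u = (dp[:, 0] * d1[:, 1] - dp[:, 1] * d1[:, 0]) / denom
    eps = 1e-12
    ok = np.abs(denom) > eps
    return ok & (t > eps) & (t < 1 - eps) & (u > eps) & (u < 1 - eps)


def polyline_self_intersects(points: np.ndarray, closed: bool = True) -> bool:
    """Brute-force O(n^2) pairwise segment self-intersection check."""
    pts = np.asarray(points, float)
    if closed and not np.allclose(pts[0], pts[-1]):
        pts = np.vstack([pts, pts[:1]])
    a, b = pts[:-1], pts[1:]
    n = a.shape[0]
    i, j = np.triu_indices(n, k=2)
    if closed:  # first and last segments are adjacent through the wrap
        keep = ~((i == 0) & (j == n - 1))
        i, j = i[keep], j[keep]
    if i.size == 0:
        return False
    hits = _segments_intersect(a[i], b[i], a[j], b[j])
    return bool(hits.any())


def _periodic_self_intersects(open_pts: np.ndarray, period: float) -> bool:
    """Self-intersection of a curve periodic in its first coordinate."""
    base = np.vstack([open_pts, open_pts[:1] + [period, 0.0]])
    if polyline_self_intersects(base, closed=False):
        return True
    # check the seam region against a shifted copy
    shifted = base.copy()
    shifted[:, 0] -= period
    a, b = base[:-1], base[1:]
    c, d = shifted[:-1], shifted[1:]
    n = a.shape[0]
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    i, j = i.ravel(), j.ravel()
    adjacent = (i == 0) & (j == n - 1)  # wrap adjacency
    keep = ~adjacent & (i != j)
    hits = _segments_intersect(a[i[keep]], b[i[keep]], c[j[keep]], d[j[keep]])
    return bool(hits.any())


def _offset_polyline(pts: np.ndarray, d: float, period: float) -> np.ndarray:
    """Offset an open periodic polyline by d along its left vertex normals."""
    ext = np.vstack(
        [pts[-1:] - [period, 0.0], pts, pts[:1] + [period, 0.0]]
    )
    seg = np.diff(ext, axis=0)
    seg_n = np.column_stack([-seg[:, 1], seg[:, 0]])
    norms = np.linalg.norm(seg_n, axis=1, keepdims=True)
    seg_n = seg_n / np.where(norms > 0, norms, 1.0)
    vn = seg_n[:-1] + seg_n[1:]
    vnorm = np.linalg.norm(vn, axis=1, keepdims=True)
    vn = vn / np.where(vnorm > 1e-12, vnorm, 1.0)
    # miter scaling so flat regions offset by exactly d
    cos_half = np.clip((vnorm / 2.0).ravel(), 0.2, 1.0)
    return pts + d * vn / cos_half[:, None]


def max_safe_offset(
    curve: SutureCurve, tol: float = 1e-3, max_iter: int = 60
) -> float:
    """Largest normal-offset half-thickness keeping the suture simple.

    The suture is developed onto the unrolled ``(theta * r, z)`` plane, offset
    along both vertex-normal directions, and tested for self-intersection
    with a brute-force pairwise segment check; the limit is located by
    bisection.  Frilled (high-iteration Koch) curves lose simplicity at small
    offsets, which is what bounds the feasible septal thickness.
    """
    if not curve.is_simple():
        raise GeometryError("input suture is not simple")
    period = 2.0 * np.pi * curve.cylinder_radius
    pts = curve.unrolled()[:-1]

    def simple_at(d: float) -> bool:
        for sgn in (+1.0, -1.0):
            off = _offset_polyline(pts, sgn * d, period)
            if _periodic_self_intersects(off, period):
                return False
        return True

    cap = max(curve.cylinder_radius, 2.0 * np.ptp(pts[:, 1]))
    lo, hi = 0.0, cap
    if simple_at(cap):
        return cap
    # shrink hi to a failing value close to the transition
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if simple_at(mid):
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(hi, 1e-9):
            break
    return lo
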