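"""Stress post-processing of solved phragmocone models.

Turns nodal/element stress tensors into the quantities reported in
comparative septal-mechanics work: cylindrical stress components (radial,
tangential/hoop, longitudinal), maximum principal stress, axial line probes
on the outer shell surface, per-region mean +- sd statistics, the thin-wall
validation error, septum-centre displacement, and the depth-equivalence
derived from linear stress-pressure trend lines.

Sign convention: tension positive, compression negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, SamplingError
from .fem import ElasticSolution
from .mesh import FEMesh

__all__ = [
    "CylStress",
    "ProbeResult",
    "RegionStats",
    "hoop_stress_theory",
    "voigt_to_tensor",
    "to_cylindrical",
    "max_principal",
    "line_probe",
    "validation_error",
    "region_stats",
    "septum_centre_displacement",
    "depth_equivalent",
]

SEAWATER_DENSITY = 1025.0  # kg / m^3
GRAVITY = 9.81  # m / s^2


@dataclass
class CylStress:
    """Cylindrical normal stress components at sample points (MPa)."""

    radial: np.ndarray
    tangential: np.ndarray
    longitudinal: np.ndarray


@dataclass
class ProbeResult:
    """Stress sampled along an axial line on the outer shell surface."""

    positions: np.ndarray  # mm along the cylinder axis
    tangential: np.ndarray  # MPa
    max_principal: np.ndarray  # MPa
    theta: float  # angular station of the probe line

    def __post_init__(self):
        if np.any(np.diff(self.positions) <= 0):
            raise SamplingError("probe positions must be strictly increasing")


@dataclass
class RegionStats:
    """Mean +- sd and peak of maximum principal stress over a region."""

    region: str
    pressure: float  # MPa
    mean_max_principal: float
    sd: float
    peak: float
    n_samples: int

    def __post_init__(self):
        if self.sd < 0 or self.peak < self.mean_max_principal - 1e-9:
            raise SamplingError("inconsistent region statistics")


# --------------------------------------------------------------------------
# pointwise operations
# --------------------------------------------------------------------------

def hoop_stress_theory(pressure: float, radius: float, thickness: float) -> float:
    """Thin-walled pressure-vessel hoop stress magnitude, sigma_h = P r / t."""
    if thickness <= 0:
        raise ParameterError("thickness must be positive")
    return pressure * radius / thickness


def voigt_to_tensor(voigt: np.ndarray) -> np.ndarray:
    """(..., 6) Voigt [xx yy zz xy yz zx] -> (..., 3, 3) symmetric tensor."""
    v = np.asarray(voigt, float)
    t = np.zeros(v.shape[:-1] + (3, 3))
    t[..., 0, 0] = v[..., 0]
    t[..., 1, 1] = v[..., 1]
    t[..., 2, 2] = v[..., 2]
    t[..., 0, 1] = t[..., 1, 0] = v[..., 3]
    t[..., 1, 2] = t[..., 2, 1] = v[..., 4]
    t[..., 0, 2] = t[..., 2, 0] = v[..., 5]
    return t


def to_cylindrical(
    stress: np.ndarray, points: np.ndarray, axis_point=(0.0, 0.0, 0.0),
    axis_dir=(0.0, 0.0, 1.0),
) -> CylStress:
    """Rotate Cartesian stress tensors into the local cylindrical frame.

    ``stress`` is (..., 3, 3) or (..., 6) Voigt; ``points`` the sample
    coordinates.  Points on the axis have no defined frame and raise.
    """
    sig = np.asarray(stress, float)
    if sig.shape[-1] == 6:
        sig = voigt_to_tensor(sig)
    p = np.atleast_2d(np.asarray(points, float))
    a0 = np.asarray(axis_point, float)
    ez = np.asarray(axis_dir, float)
    ez = ez / np.linalg.norm(ez)
    rel = p - a0
    rel = rel - np.outer(rel @ ez, ez)
    rn = np.linalg.norm(rel, axis=-1)
    if np.any(rn < 1e-12):
        raise SamplingError("cylindrical frame undefined on the axis")
    er = rel / rn[:, None]
    et = np.cross(ez, er)
    sig = sig.reshape(p.shape[0], 3, 3)
    rr = np.einsum("ni,nij,nj->n", er, sig, er)
    tt = np.einsum("ni,nij,nj->n", et, sig, et)
    zz = np.einsum("i,nij,j->n", ez, sig, ez)
    return CylStress(radial=rr, tangential=tt, longitudinal=zz)


def max_principal(stress: np.ndarray) -> np.ndarray:
    """Largest eigenvalue of symmetric stress tensors ((...,3,3) or (...,6))."""
    sig = np.asarray(stress, float)
    if sig.shape[-1] == 6:
        sig = voigt_to_tensor(sig)
    if not np.allclose(sig, np.swapaxes(sig, -1, -2), atol=1e-8 * max(1.0, np.abs(sig).max())):
        raise ParameterError("stress tensor must be symmetric")
    return np.linalg.eigvalsh(sig)[..., -1]


# --------------------------------------------------------------------------
# model-level sampling
# --------------------------------------------------------------------------

def _outer_wall_samples(mesh: FEMesh):
    ids = mesh.set("outer_cyl")
    if ids.size == 0:
        raise SamplingError("mesh has no outer cylindrical surface nodes")
    return ids


def line_probe(
    solution: ElasticSolution,
    mesh: FEMesh,
    theta: float | None = None,
    n_samples: int | None = None,
) -> ProbeResult:
    """Axial line probe along the outer shell surface at angle ``theta``.

    Sampling uses the column of outer-surface nodes nearest to ``theta``
    (the structured mesh provides an exact axial node line), from cap
    junction to cap junction.  Default theta is the first primary-lobe
    mirror axis, theta = 0.
    """
    if theta is None:
        theta = 0.0
    ids = _outer_wall_samples(mesh)
    pos = mesh.nodes[ids]
    th = np.mod(np.arctan2(pos[:, 1], pos[:, 0]), 2.0 * np.pi)
    frac = mesh.meta.get("symmetry_fraction", 1.0)
    alpha = mesh.meta.get("sector_angle", 2.0 * np.pi)
    tq = np.mod(theta, 2.0 * np.pi)
    if frac < 1.0:
        # fold the query angle into the meshed sector (mirror symmetry)
        tq = np.mod(tq, 2.0 * alpha)
        if tq > alpha:
            tq = 2.0 * alpha - tq
    dth = np.abs(th - tq)
    dth = np.minimum(dth, 2.0 * np.pi - dth)
    tol = 0.51 * alpha / max(1, mesh.meta.get("n_cols", 16))
    col_th = th[np.argmin(dth)]
    on_col = np.abs(th - col_th) < 1e-9
    sel = ids[on_col]
    order = np.argsort(mesh.nodes[sel, 2])
    sel = sel[order]
    z = mesh.nodes[sel, 2]
    sig = solution.nodal_stress[sel]
    cyl = to_cylindrical(sig, mesh.nodes[sel])
    mp = max_principal(sig)
    if n_samples is not None and n_samples < sel.size:
        pick = np.unique(np.linspace(0, sel.size - 1, n_samples).astype(int))
        z, mp = z[pick], mp[pick]
        cyl = CylStress(cyl.radial[pick], cyl.tangential[pick], cyl.longitudinal[pick])
    return ProbeResult(
        positions=z, tangential=cyl.tangential, max_principal=mp, theta=float(col_th)
    )


def validation_band(mesh: FEMesh, width: float = 2.0):
    """Outer-surface node band midway between outermost septum and cap."""
    cfg = mesh.meta.get("config")
    L = mesh.meta["length"]
    septa = mesh.meta.get("septa", [])
    if septa:
        amp = cfg.suture.resolve_amplitude(cfg.inner_radius) if cfg else 0.0
        z_edge = max(s["centre_z"] for s in septa) + amp / 2.0
    else:
        z_edge = L / 2.0
    mid = 0.5 * (z_edge + L)
    ids = _outer_wall_samples(mesh)
    z = mesh.nodes[ids, 2]
    band = ids[(z > mid - width / 2.0) & (z < mid + width / 2.0)]
    if band.size == 0:
        raise SamplingError(
            "no outer-wall nodes in the validation band; end_margin too small"
        )
    return band


def validation_error(solution: ElasticSolution, config=None, width: float = 2.0) -> float:
    """Percent deviation of sampled hoop stress from the thin-wall formula.

    Mean hoop (tangential) stress magnitude over outer-surface nodes in a
    band midway between the outermost septum and the cap, compared with
    ``P r / t`` using the inner radius (the pressure-vessel convention of the
    reference protocol).
    """
    mesh = solution.mesh
    cfg = config or mesh.meta.get("config")
    band = validation_band(mesh, width=width)
    cyl = to_cylindrical(solution.nodal_stress[band], mesh.nodes[band])
    sampled = float(np.abs(cyl.tangential.mean()))
    theory = hoop_stress_theory(
        solution.pressure, cfg.inner_radius, cfg.shell_thickness
    )
    return abs(sampled - theory) / theory * 100.0


def region_stats(
    solution: ElasticSolution,
    mesh: FEMesh,
    region: str,
    pressure: float | None = None,
) -> RegionStats:
    """Mean, sd and peak maximum principal stress over a sampling region.

    ``region`` is either ``"shell_wall"`` (external surface nodes within one
    septal spacing of the middle septum, excluding caps) or a septum label
    such as ``"septum_2"`` (all nodes of that septum's elements).  Exterior
    septa are poor proxies for an arbitrary mid-phragmocone septum, so
    shell-wall statistics are anchored on the middle septum.
    """
    if pressure is not None and not np.isclose(pressure, solution.pressure):
        solution = solution.scaled(pressure)
    cfg = mesh.meta.get("config")
    if region == "shell_wall":
        ids = _outer_wall_samples(mesh)
        z = mesh.nodes[ids, 2]
        if cfg is not None and cfg.n_septa:
            z_mid = mesh.meta["length"] / 2.0
            span = cfg.septal_spacing
            ids = ids[(z > z_mid - span) & (z < z_mid + span)]
        if ids.size == 0:
            raise SamplingError("empty shell-wall sampling band")
        vals = max_principal(solution.nodal_stress[ids])
    else:
        if region not in mesh.region_names:
            raise SamplingError(f"unknown region {region!r}")
        ids = mesh.nodes_of_region(region)
        vals = max_principal(solution.nodal_stress[ids])
    return RegionStats(
        region=region,
        pressure=float(solution.pressure),
        mean_max_principal=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        peak=float(vals.max()),
        n_samples=int(vals.size),
    )


def middle_septum(mesh: FEMesh) -> str:
    septa = mesh.meta.get("septa", [])
    if not septa:
        raise SamplingError("model has no septa")
    return f"septum_{(len(septa) - 1) // 2}"


def septum_centre_displacement(
    solution: ElasticSolution, mesh: FEMesh, septum_id: str | int | None = None
) -> float:
    """Displacement magnitude (micrometres) at a septum's area centre.

    Samples the node of the septum region closest to the cylinder axis (the
    apex of the septal disc).
    """
    if septum_id is None:
        region = middle_septum(mesh)
    elif isinstance(septum_id, int):
        region = f"septum_{septum_id}"
    else:
        region = septum_id
    if region not in mesh.region_names:
        raise SamplingError(f"unknown septum label {region!r}")
    ids = mesh.nodes_of_region(region)
    r = np.hypot(mesh.nodes[ids, 0], mesh.nodes[ids, 1])
    centre = ids[np.argmin(r)]
    u = solution.displacements[centre]
    return float(np.linalg.norm(u) * 1000.0)  # mm -> um


def depth_equivalent(
    stats_a: list[RegionStats],
    stats_b: list[RegionStats],
    reference_pressure: float = 2.0,
    seawater_density: float = SEAWATER_DENSITY,
    g: float = GRAVITY,
) -> tuple[float, float]:
    """Pressure (and extra depth) at which model B matches model A's stress.

    Ordinary-least-squares lines of mean shell-wall maximum principal stress
    versus pressure are fitted per model; the returned pressure solves
    ``line_B(P) = line_A(reference_pressure)`` and the depth increment is
    ``(P - reference_pressure) / (rho g)``.
    """
    def fit(stats):
        p = np.array([s.pressure for s in stats], float)
        y = np.array([s.mean_max_principal for s in stats], float)
        if p.size < 2:
            raise ParameterError("need at least two pressure levels per model")
        slope, intercept = np.polyfit(p, y, 1)
        if abs(slope) < 1e-12:
            raise ParameterError("degenerate (zero-slope) stress trend")
        return slope, intercept

    sa, ia = fit(stats_a)
    sb, ib = fit(stats_b)
    target = sa * reference_pressure + ia
    pressure = (target - ib) / sb
    extra_depth = (pressure - reference_pressure) * 1e6 / (seawater_density * g)
    return float(pressure), float(extra_depth)
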