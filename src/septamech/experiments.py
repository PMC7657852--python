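"""Model suites, analytic benchmark fixtures and suite orchestration.

The default suite regenerates the reference 11-geometry factorial design:

* septal spacing -- sexilobate septa at 5, 10 and 20 mm (5, 3 and 2 septa);
* shell thickness -- trilobate and sexilobate at 0.1 and 0.5 mm walls;
* lobate complexity -- 3 to 6 primary lobes at the 0.5 mm wall;
* Koch complexity -- fractal iterations 1-3 (0.04 mm septa), each analysed
  at 1, 2 and 3 MPa external pressure.

Every geometry is built, meshed, solved and post-processed; the stiffness is
factorised once per geometry and the pressure series reuses the
factorisation (the model is linear, so each pressure's right-hand side is
solved exactly).  Runs are resumable: models whose result files already
exist are skipped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis
from .analysis import line_probe, region_stats, septum_centre_displacement, to_cylindrical, validation_error
from .assembly import MaterialParams, MeshParams, ModelConfig, build_shell, tet_mesh
from .errors import ParameterError
from .fem import Constraints, PressureLoad, solve, solve_pressure_series
from .mesh import CellComplex, FEMesh, tetrahedralize
from .septum import min_curvature_surface
from .suture import PlanarCurve, SutureSpec, wrap_on_cylinder

__all__ = [
    "SuiteSpec",
    "Fixture",
    "run_suite",
    "make_fixture",
    "compare_models",
    "paper_suite",
]


# --------------------------------------------------------------------------
# suite specification
# --------------------------------------------------------------------------

@dataclass
class SuiteSpec:
    """Named model configurations plus their pressure series."""

    models: dict = field(default_factory=dict)  # name -> ModelConfig
    pressures: dict = field(default_factory=dict)  # name -> tuple of MPa
    mesh: MeshParams = field(default_factory=MeshParams.coarse)
    mesh_overrides: dict = field(default_factory=dict)  # name -> MeshParams
    sector: bool = True

    def add(self, name: str, config: ModelConfig, pressures=(2.0,), mesh=None):
        self.models[name] = config
        self.pressures[name] = tuple(pressures)
        if mesh is not None:
            self.mesh_overrides[name] = mesh

    def mesh_for(self, name: str) -> MeshParams:
        return self.mesh_overrides.get(name, self.mesh)


def paper_suite(tier: str = "coarse") -> SuiteSpec:
    """The reference 11-geometry suite (see module docstring)."""
    mp = MeshParams.coarse() if tier == "coarse" else MeshParams.fine()
    spec = SuiteSpec(mesh=mp)

    def lobate(n):
        return SutureSpec(family="lobate", n_lobes=n)

    # lobate complexity suite, 0.5 mm wall, 5 septa at 5 mm
    for n in (3, 4, 5, 6):
        spec.add(
            SutureSpec(family="lobate", n_lobes=n).label(),
            ModelConfig(suture=lobate(n)),
        )
    # shell thickness suite: 0.1 mm walls for tri- and sexilobate
    for n in (3, 6):
        spec.add(
            f"{lobate(n).label()}_thin",
            ModelConfig(suture=lobate(n), shell_thickness=0.1),
        )
    # septal spacing suite: sexilobate at 10 and 20 mm (5 mm is above)
    for spacing, n_septa in ((10.0, 3), (20.0, 2)):
        spec.add(
            f"sexilobate_s{spacing:g}",
            ModelConfig(suture=lobate(6), septal_spacing=spacing, n_septa=n_septa),
        )
    # Koch suite: iterations 1-3, thin septa, pressure series; all three
    # iterations are meshed at the angular resolution the third one needs,
    # so cross-iteration comparisons are not confounded by mesh density
    n_theta_koch = int(np.ceil(spec.mesh.theta_per_segment * 4**3 * 4))
    for it in (1, 2, 3):
        segs = 4**it * 4
        spec.add(
            f"koch{it}",
            ModelConfig(
                suture=SutureSpec(family="koch", iterations=it),
                septal_thickness=0.04,
            ),
            pressures=(1.0, 2.0, 3.0),
            mesh=replace(spec.mesh, theta_per_segment=n_theta_koch / segs),
        )
    assert len(spec.models) == 11
    return spec


# --------------------------------------------------------------------------
# suite runner
# --------------------------------------------------------------------------

def _analyse_model(name, config, mesh, solutions):
    rows = []
    septum_mid = analysis.middle_septum(mesh) if config.n_septa else None
    for sol in solutions:
        row = {
            "model": name,
            "pressure_MPa": sol.pressure,
            "n_elements": mesh.n_elements,
            "n_nodes": mesh.n_nodes,
            "strain_energy_mJ": sol.strain_energy
            / mesh.meta.get("symmetry_fraction", 1.0),
            "validation_error_pct": validation_error(sol, config),
        }
        ws = region_stats(sol, mesh, "shell_wall")
        row.update(
            wall_mean_mp_MPa=ws.mean_max_principal,
            wall_sd_mp_MPa=ws.sd,
            wall_peak_mp_MPa=ws.peak,
        )
        # mean hoop magnitude over the same shell-wall band
        ids = mesh.set("outer_cyl")
        z = mesh.nodes[ids, 2]
        if config.n_septa:
            z_mid = mesh.meta["length"] / 2.0
            ids = ids[(z > z_mid - config.septal_spacing) & (z < z_mid + config.septal_spacing)]
        cyl = to_cylindrical(sol.nodal_stress[ids], mesh.nodes[ids])
        row["wall_tangential_mean_MPa"] = float(np.abs(cyl.tangential).mean())
        row["wall_tangential_peak_MPa"] = float(np.abs(cyl.tangential).max())
        if septum_mid is not None:
            ss = region_stats(sol, mesh, septum_mid)
            row.update(
                septum_mean_mp_MPa=ss.mean_max_principal,
                septum_sd_mp_MPa=ss.sd,
                septum_peak_mp_MPa=ss.peak,
                septum_centre_displacement_um=septum_centre_displacement(
                    sol, mesh, septum_mid
                ),
            )
        rows.append(row)
    return rows


def run_suite(spec: SuiteSpec, out_dir: str | Path | None = None) -> pd.DataFrame:
    """Build, mesh, solve and post-process every model of a suite.

    Returns one row per model x pressure.  With ``out_dir`` set, per-model
    JSON results and probe CSVs are written and already-completed models are
    skipped on re-runs.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    all_rows = []
    for name, config in spec.models.items():
        cache = out / f"{name}.json" if out is not None else None
        if cache is not None and cache.exists():
            all_rows.extend(json.loads(cache.read_text())["rows"])
            continue
        try:
            solid = build_shell(config, spec.mesh_for(name), sector=spec.sector)
            mesh = tet_mesh(solid)
            sols = solve_pressure_series(mesh, config.material, spec.pressures[name])
            rows = _analyse_model(name, config, mesh, sols)
        except Exception as exc:  # record the failure, keep the suite going
            rows = [{"model": name, "error": f"{type(exc).__name__}: {exc}"}]
        if cache is not None:
            payload = {"rows": rows, "config_label": config.label()}
            cache.write_text(json.dumps(payload, indent=1))
            if "error" not in rows[0]:
                probe = line_probe(sols[-1], mesh)
                pd.DataFrame(
                    {
                        "position_mm": probe.positions,
                        "tangential_MPa": probe.tangential,
                        "max_principal_MPa": probe.max_principal,
                    }
                ).to_csv(out / f"{name}_probe.csv", index=False)
        all_rows.extend(rows)
    df = pd.DataFrame(all_rows)
    if out is not None:
        df.to_csv(out / "suite_results.csv", index=False)
    return df


def compare_models(
    results: pd.DataFrame, model_a: str, model_b: str, quantity: str
) -> pd.DataFrame:
    """Percent change of ``quantity`` from model A to model B per pressure."""
    a = results[results.model == model_a]
    b = results[results.model == model_b]
    if a.empty or b.empty:
        raise ParameterError("both models must be present in the results")
    merged = a.merge(b, on="pressure_MPa", suffixes=("_a", "_b"))
    if merged.empty:
        raise ParameterError("models were not analysed at matching pressures")
    qa, qb = merged[f"{quantity}_a"], merged[f"{quantity}_b"]
    return pd.DataFrame(
        {
            "pressure_MPa": merged.pressure_MPa,
            f"{quantity}_a": qa,
            f"{quantity}_b": qb,
            "percent_change": (qb - qa) / qa.abs() * 100.0,
        }
    )


# --------------------------------------------------------------------------
# analytic fixtures
# --------------------------------------------------------------------------

@dataclass
class Fixture:
    """A benchmark geometry with its closed-form truth."""

    name: str
    mesh: FEMesh
    truth: dict
    load: PressureLoad
    constraints: Constraints | None = None
    material: MaterialParams = field(default_factory=MaterialParams)

    def solve(self):
        return solve(self.mesh, self.material, self.load, self.constraints)


def _hex_faces(v):
    return [
        (v[0], v[1], v[2], v[3]),
        (v[4], v[5], v[6], v[7]),
        (v[0], v[1], v[5], v[4]),
        (v[1], v[2], v[6], v[5]),
        (v[2], v[3], v[7], v[6]),
        (v[3], v[0], v[4], v[7]),
    ]


def _cube_mesh(n: int, order: int = 2) -> FEMesh:
    cx = CellComplex()
    cx.meta["external_tags"] = ["surf"]

    def node(i, j, k):
        tags = ["surf"] if (i in (0, n) or j in (0, n) or k in (0, n)) else []
        return cx.node(("b", i, j, k), (i / n, j / n, k / n), tags)

    for i in range(n):
        for j in range(n):
            for k in range(n):
                v = [
                    node(i, j, k),
                    node(i + 1, j, k),
                    node(i + 1, j + 1, k),
                    node(i, j + 1, k),
                    node(i, j, k + 1),
                    node(i + 1, j, k + 1),
                    node(i + 1, j + 1, k + 1),
                    node(i, j + 1, k + 1),
                ]
                cx.add_cell("cube", _hex_faces(v))
    return tetrahedralize(cx, order=order)


def _annulus_mesh(
    r_i: float, r_o: float, length: float, n_theta: int, n_z: int, n_r: int,
    order: int = 2,
) -> FEMesh:
    cx = CellComplex()
    cx.meta["external_tags"] = ["outer_cyl"]
    cx.surfaces["outer_cyl"] = ("cyl", r_o)
    cx.surfaces["inner_cyl"] = ("cyl", r_i)
    radii = r_i + np.arange(n_r + 1) * (r_o - r_i) / n_r
    theta = np.arange(n_theta) * 2.0 * np.pi / n_theta

    def node(j, i, k):
        jj = j % n_theta
        tags = []
        if i == 0:
            tags.append("inner_cyl")
        if i == n_r:
            tags.append("outer_cyl")
        if k == 0:
            tags.append("z0")
        if k == n_z:
            tags.append("z1")
        pos = (
            radii[i] * np.cos(theta[jj]),
            radii[i] * np.sin(theta[jj]),
            length * k / n_z,
        )
        return cx.node(("a", jj, i, k), pos, tags)

    for k in range(n_z):
        for j in range(n_theta):
            for i in range(n_r):
                v = [
                    node(j, i, k),
                    node(j + 1, i, k),
                    node(j + 1, i + 1, k),
                    node(j, i + 1, k),
                    node(j, i, k + 1),
                    node(j + 1, i, k + 1),
                    node(j + 1, i + 1, k + 1),
                    node(j, i + 1, k + 1),
                ]
                cx.add_cell("annulus", _hex_faces(v))
    return tetrahedralize(cx, order=order)


def _sphere_mesh(
    r_mid: float, thickness: float, n_theta: int, n_phi: int, n_r: int,
    order: int = 2,
) -> FEMesh:
    r_i = r_mid - thickness / 2.0
    r_o = r_mid + thickness / 2.0
    cx = CellComplex()
    cx.meta["external_tags"] = ["outer_sph"]
    cx.surfaces["outer_sph"] = ("sph", (0.0, 0.0, 0.0), r_o)
    cx.surfaces["inner_sph"] = ("sph", (0.0, 0.0, 0.0), r_i)
    radii = r_i + np.arange(n_r + 1) * thickness / n_r
    theta = np.arange(n_theta) * 2.0 * np.pi / n_theta
    phi = -0.5 * np.pi + np.arange(n_phi + 1) * (np.pi / n_phi)

    def node(j, i, l):
        tags = []
        if i == 0:
            tags.append("inner_sph")
        if i == n_r:
            tags.append("outer_sph")
        if l in (0, n_phi):  # poles
            sgn = -1.0 if l == 0 else 1.0
            return cx.node(("p", sgn, i), (0.0, 0.0, sgn * radii[i]), tags)
        jj = j % n_theta
        pos = (
            radii[i] * np.cos(phi[l]) * np.cos(theta[jj]),
            radii[i] * np.cos(phi[l]) * np.sin(theta[jj]),
            radii[i] * np.sin(phi[l]),
        )
        return cx.node(("s", jj, i, l), pos, tags)

    for l in range(n_phi):
        for j in range(n_theta):
            for i in range(n_r):
                if l == 0:
                    a0 = node(j, i, 1)
                    a1 = node(j + 1, i, 1)
                    a2 = node(j + 1, i + 1, 1)
                    a3 = node(j, i + 1, 1)
                    p0 = node(j, i, 0)
                    p1 = node(j, i + 1, 0)
                    faces = [
                        (a0, a1, a2, a3),
                        (a0, a1, p0),
                        (a3, a2, p1),
                        (a0, a3, p1, p0),
                        (a1, a2, p1, p0),
                    ]
                elif l == n_phi - 1:
                    a0 = node(j, i, l)
                    a1 = node(j + 1, i, l)
                    a2 = node(j + 1, i + 1, l)
                    a3 = node(j, i + 1, l)
                    p0 = node(j, i, n_phi)
                    p1 = node(j, i + 1, n_phi)
                    faces = [
                        (a0, a1, a2, a3),
                        (a0, a1, p0),
                        (a3, a2, p1),
                        (a0, a3, p1, p0),
                        (a1, a2, p1, p0),
                    ]
                else:
                    v = [
                        node(j, i, l),
                        node(j + 1, i, l),
                        node(j + 1, i + 1, l),
                        node(j, i + 1, l),
                        node(j, i, l + 1),
                        node(j + 1, i, l + 1),
                        node(j + 1, i + 1, l + 1),
                        node(j, i + 1, l + 1),
                    ]
                    faces = _hex_faces(v)
                cx.add_cell("sphere", faces)
    return tetrahedralize(cx, order=order)


def make_fixture(name: str, **params) -> Fixture:
    """Construct an analytic benchmark fixture.

    Supported names: ``hydrostatic_cube``, ``capped_cylinder``,
    ``lame_cylinder``, ``pressurized_sphere``, ``flat_disc_boundary``.
    """
    if name == "hydrostatic_cube":
        P = params.get("pressure", 2.0)
        mesh = _cube_mesh(params.get("n", 2), params.get("order", 2))
        facets = mesh.external_facets
        return Fixture(
            name=name,
            mesh=mesh,
            truth={"stress_tensor": -P * np.eye(3)},
            load=PressureLoad(P, facets),
        )

    if name == "capped_cylinder":
        P = params.get("pressure", 2.0)
        r = params.get("inner_radius", 9.11)
        t = params.get("thickness", 0.5)
        config = ModelConfig(
            inner_radius=r,
            shell_thickness=t,
            n_septa=0,
            pressure=P,
            end_margin=params.get("end_margin", 20.0),
        )
        mp = params.get("mesh_params") or MeshParams.coarse()
        mesh = tet_mesh(build_shell(config, mp, sector=params.get("sector", True)))
        return Fixture(
            name=name,
            mesh=mesh,
            truth={"hoop": analysis.hoop_stress_theory(P, r, t)},
            load=PressureLoad(P),
        )

    if name == "lame_cylinder":
        P = params.get("pressure", 2.0)
        r_i = params.get("inner_radius", 5.0)
        r_o = params.get("outer_radius", 10.0)
        length = params.get("length", 4.0)
        mesh = _annulus_mesh(
            r_i,
            r_o,
            length,
            n_theta=params.get("n_theta", 32),
            n_z=params.get("n_z", 2),
            n_r=params.get("n_r", 4),
            order=params.get("order", 2),
        )
        # plane strain: no axial displacement anywhere; in-plane rigid modes
        # pinned at two diametrically opposite nodes
        fixed = [(int(n), 2) for n in range(mesh.n_nodes)]
        pts = mesh.nodes
        na = int(np.argmin(np.abs(pts[:, 1]) + np.abs(pts[:, 0] - r_i)))
        nb = int(np.argmin(np.abs(pts[:, 1]) + np.abs(pts[:, 0] + r_i)))
        fixed += [(na, 0), (na, 1), (nb, 1)]

        def hoop(rr):
            rr = np.asarray(rr, float)
            return -P * r_o**2 * (1.0 + r_i**2 / rr**2) / (r_o**2 - r_i**2)

        def radial(rr):
            rr = np.asarray(rr, float)
            return -P * r_o**2 * (1.0 - r_i**2 / rr**2) / (r_o**2 - r_i**2)

        return Fixture(
            name=name,
            mesh=mesh,
            truth={"hoop_profile": hoop, "radial_profile": radial},
            load=PressureLoad(P),
            constraints=Constraints(fixed=fixed),
        )

    if name == "pressurized_sphere":
        P = params.get("pressure", 2.0)
        r = params.get("radius", 10.0)
        t = params.get("thickness", 0.5)
        mesh = _sphere_mesh(
            r,
            t,
            n_theta=params.get("n_theta", 24),
            n_phi=params.get("n_phi", 12),
            n_r=params.get("n_r", 1),
            order=params.get("order", 2),
        )
        return Fixture(
            name=name,
            mesh=mesh,
            truth={"membrane": -P * r / (2.0 * t)},
            load=PressureLoad(P),
        )

    if name == "flat_disc_boundary":
        r = params.get("radius", 9.11)
        n = params.get("n_points", 96)
        flat = PlanarCurve(np.linspace(0.0, 1.0, n + 1), np.zeros(n + 1))
        suture = wrap_on_cylinder(flat, r)
        surf = min_curvature_surface(
            suture, target_edge_length=params.get("target_edge_length", 0.1 * r)
        )
        return Fixture(
            name=name,
            mesh=None,  # geometry-only fixture
            truth={"surface": surf, "planar_deviation": float(np.abs(surf.vertices[:, 2]).max())},
            load=PressureLoad(0.0, np.empty((0, 3), int)),
        )

    raise ParameterError(f"unknown fixture {name!r}")
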