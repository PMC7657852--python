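"""Phragmocone model assembly.

A model is a double-walled cylinder (annular shell wall between an inner and
an outer cylinder), closed at both ends by hemispherical caps of the same
wall thickness, with N thickened septa fused to the inner wall at a fixed
axial spacing, centred on the cylinder's midlength.

Assembly is *constructive and conformal*: the wall is a structured grid in
(theta, r, z) whose axial levels are warped so that, at every angular
station, two grid levels coincide with the lower and upper faces of each
septum along its suture; the septal discs reuse those wall nodes as their
boundary rings.  No boolean operations or mesh repair are needed and the
septum/wall junctions share nodes exactly.

All model suites have dihedral (mirror) symmetry: an n-lobed suture repeats
every ``pi/n`` with mirror planes through every lobe and saddle axis, and the
four-copy Koch suture every ``pi/4``.  By default only the fundamental sector
is meshed; the FEM applies symmetry boundary conditions on the two cut
planes, which is exact for the symmetric geometry and pressure load.  Full
360-degree meshing is available with ``sector=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import AssemblyError, ParameterError
from .mesh import CellComplex, FEMesh, tetrahedralize
from .septum import min_curvature_surface, plan_rings, polar_disc
from .suture import SutureSpec, wrap_on_cylinder

__all__ = [
    "MaterialParams",
    "MeshParams",
    "ModelConfig",
    "SolidMesh",
    "FEMesh",
    "build_shell",
    "tet_mesh",
]


@dataclass(frozen=True)
class MaterialParams:
    """Isotropic linear-elastic constants (mm-MPa-N unit system)."""

    youngs_modulus: float = 70000.0  # MPa (70 GPa, nacreous shell wall)
    poisson_ratio: float = 0.3

    def __post_init__(self):
        if self.youngs_modulus <= 0:
            raise ParameterError("Young's modulus must be positive")
        if not 0 <= self.poisson_ratio < 0.5:
            raise ParameterError("Poisson ratio must lie in [0, 0.5)")

    @property
    def lame(self) -> tuple[float, float]:
        e, nu = self.youngs_modulus, self.poisson_ratio
        lam = e * nu / ((1 + nu) * (1 - 2 * nu))
        mu = e / (2 * (1 + nu))
        return lam, mu


@dataclass(frozen=True)
class MeshParams:
    """Resolution controls for the constructive mesher."""

    target_size: float = 1.2  # nominal element size in mm
    n_r: int = 1  # radial element layers through the wall
    theta_per_segment: float = 1.5  # angular columns per suture segment (Koch)
    cap_factor: float = 2.0  # caps may be coarser by this factor
    order: int = 2

    @classmethod
    def coarse(cls) -> "MeshParams":
        return cls()

    @classmethod
    def fine(cls) -> "MeshParams":
        return cls(target_size=0.6, n_r=2, theta_per_segment=2.5)


@dataclass
class ModelConfig:
    """Geometry, load and material of one phragmocone model."""

    inner_radius: float = 9.11  # mm
    shell_thickness: float = 0.5  # mm (0.1 or 0.5 in the reference suite)
    septal_spacing: float = 5.0  # mm
    n_septa: int = 5
    suture: SutureSpec = field(default_factory=SutureSpec)
    septal_thickness: float = 0.4  # mm (0.04 for Koch models)
    end_margin: float = 20.0  # mm of wall beyond the outermost septa
    pressure: float = 2.0  # MPa external
    material: MaterialParams = field(default_factory=MaterialParams)

    def __post_init__(self):
        if self.inner_radius <= 0 or self.shell_thickness <= 0:
            raise ParameterError("radii and thickness must be positive")
        if self.n_septa < 0:
            raise ParameterError("n_septa must be >= 0")
        if self.n_septa and self.septal_spacing <= self.septal_thickness:
            raise ParameterError("septal spacing must exceed septal thickness")

    @property
    def outer_radius(self) -> float:
        return self.inner_radius + self.shell_thickness

    @property
    def length(self) -> float:
        span = (self.n_septa - 1) * self.septal_spacing if self.n_septa else 0.0
        return span + 2.0 * self.end_margin

    def septum_centres(self) -> np.ndarray:
        if self.n_septa == 0:
            return np.empty(0)
        offs = (np.arange(self.n_septa) - (self.n_septa - 1) / 2.0) * self.septal_spacing
        return self.length / 2.0 + offs

    def label(self) -> str:
        if self.n_septa == 0:
            return f"cylinder_t{self.shell_thickness:g}"
        return (
            f"{self.suture.label()}_t{self.shell_thickness:g}"
            f"_s{self.septal_spacing:g}"
        )


@dataclass
class SolidMesh:
    """Watertight assembled solid as a labelled cell complex."""

    complex: CellComplex
    config: ModelConfig
    mesh_params: MeshParams
    sector: bool
    sector_angle: float  # radians meshed (2*pi when sector=False)

    @property
    def symmetry_fraction(self) -> float:
        return self.sector_angle / (2.0 * np.pi)

    def is_watertight(self) -> bool:
        return self.complex.is_watertight()

    def boundary_trimesh(self):
        import trimesh

        tm = trimesh.Trimesh(
            vertices=self.complex.node_array(),
            faces=self.complex.boundary_triangles(),
            process=False,
        )
        trimesh.repair.fix_normals(tm)
        return tm

    def export_stl(self, path):
        self.boundary_trimesh().export(path)


# --------------------------------------------------------------------------
# builder
# --------------------------------------------------------------------------

def _resolve_angular(config: ModelConfig, mp: MeshParams, sector: bool):
    """Choose the sector angle and angular column count."""
    if config.n_septa == 0:
        n_primary = 4  # arbitrary for an axisymmetric shell
        planar = None
    else:
        planar = config.suture.make_planar(config.inner_radius).centred()
        n_primary = config.suture.n_primary
    m = 2 * n_primary  # number of mirror sectors
    two_pi_r = 2.0 * np.pi * config.inner_radius
    n_full = int(np.ceil(two_pi_r / mp.target_size))
    if planar is not None and config.suture.family == "koch":
        segs = 4 ** config.suture.iterations * config.suture.n_copies
        n_full = max(n_full, int(np.ceil(mp.theta_per_segment * segs)))
    n_sec = max(4, int(np.ceil(n_full / m)))
    n_sec = 4 * int(np.ceil(n_sec / 4))  # divisible by the disc ring divisors
    n_full = m * n_sec
    angle = 2.0 * np.pi / m if sector else 2.0 * np.pi
    return planar, m, n_sec, n_full, angle


def build_shell(
    config: ModelConfig,
    mesh_params: MeshParams | None = None,
    sector: bool = True,
) -> SolidMesh:
    """Assemble the capped, septate shell into a watertight labelled solid."""
    mp = mesh_params or MeshParams.coarse()
    r_i, r_o = config.inner_radius, config.outer_radius
    t_w = config.shell_thickness
    L = config.length
    h = config.septal_thickness / 2.0

    planar, m, n_sec, n_full, angle = _resolve_angular(config, mp, sector)
    n_cols = n_sec if sector else n_full  # angular cell columns
    wrap = not sector

    amp = planar.amplitude if planar is not None else 0.0
    if config.n_septa and config.end_margin < amp / 2.0 + h + 0.5:
        raise AssemblyError(
            "end_margin too small for the suture amplitude and septal thickness"
        )

    cx = CellComplex()
    cx.meta.update(
        inner_radius=r_i,
        outer_radius=r_o,
        length=L,
        sector=sector,
        sector_angle=angle,
        external_tags=["outer_cyl", "cap_bottom_outer", "cap_top_outer"],
    )
    cx.surfaces["outer_cyl"] = ("cyl", r_o)
    cx.surfaces["inner_cyl"] = ("cyl", r_i)
    cx.surfaces["cap_bottom_outer"] = ("sph", (0.0, 0.0, 0.0), r_o)
    cx.surfaces["cap_bottom_inner"] = ("sph", (0.0, 0.0, 0.0), r_i)
    cx.surfaces["cap_top_outer"] = ("sph", (0.0, 0.0, L), r_o)
    cx.surfaces["cap_top_inner"] = ("sph", (0.0, 0.0, L), r_i)

    theta = (
        np.arange(n_cols + 1) * (angle / n_sec)
        if sector
        else np.arange(n_cols) * (2.0 * np.pi / n_full)
    )
    n_theta_nodes = theta.size
    cos_t, sin_t = np.cos(theta), np.sin(theta)

    # ---- axial levels -----------------------------------------------------
    # each level is an array over angular columns; two consecutive levels
    # bracket each septum along its (theta-dependent) suture position
    y = planar.interp(theta / (2.0 * np.pi)) if planar is not None else None
    # the septum meets the wall in a band whose axial height grows with the
    # suture slope (a slab of normal thickness t cut by the cylinder spans
    # t*sec(slope) axially); the offset surfaces themselves are built along
    # true surface normals so the septum keeps uniform normal thickness
    if planar is not None:
        dy = np.gradient(planar.y, planar.x)
        slope = np.interp(np.mod(theta / (2.0 * np.pi), 1.0), planar.x, dy) / (
            2.0 * np.pi * r_i
        )
        h_col = np.minimum(h * np.sqrt(1.0 + slope**2), 0.2 * config.septal_spacing)
    else:
        h_col = None
    const = lambda z: np.full(n_theta_nodes, z)  # noqa: E731
    breakpoints: list[tuple[np.ndarray, str | None]] = [(const(0.0), None)]
    for s, zc in enumerate(config.septum_centres()):
        breakpoints.append((zc + y - h_col, f"septum_{s}_lo"))
        breakpoints.append((zc + y + h_col, f"septum_{s}_hi"))
    breakpoints.append((const(L), None))

    levels: list[np.ndarray] = []
    level_tag: dict[str, int] = {}
    for b, (arr, tag) in enumerate(breakpoints):
        if b > 0:
            prev_arr, prev_tag = breakpoints[b - 1]
            gap = float(np.mean(arr - prev_arr))
            if gap < -1e-9:
                raise AssemblyError("septa overlap: spacing too small")
            inside_septum = tag is not None and prev_tag is not None and tag[:-3] == prev_tag[:-3]
            n_fill = 0 if inside_septum else int(max(0, round(gap / mp.target_size) - 1))
            for f in range(1, n_fill + 1):
                levels.append(prev_arr + (arr - prev_arr) * (f / (n_fill + 1)))
        levels.append(arr.copy())
        if tag is not None:
            level_tag[tag] = len(levels) - 1
    z_levels = np.asarray(levels)  # (K, n_theta_nodes)
    n_k = z_levels.shape[0]

    radii_w = r_i + np.arange(mp.n_r + 1) * (t_w / mp.n_r)

    # ---- wall nodes and cells --------------------------------------------
    def wall_node(j, i, k):
        jj = j % n_full if wrap else j
        tags = []
        if i == 0:
            tags.append("inner_cyl")
        if i == mp.n_r:
            tags.append("outer_cyl")
        if sector and jj == 0:
            tags.append("mirror0")
        if sector and jj == n_sec:
            tags.append("mirror1")
        pos = (radii_w[i] * cos_t[jj], radii_w[i] * sin_t[jj], z_levels[k, jj])
        return cx.node(("w", jj, i, k), pos, tags)

    hex_faces = lambda v: [  # noqa: E731
        (v[0], v[1], v[2], v[3]),
        (v[4], v[5], v[6], v[7]),
        (v[0], v[1], v[5], v[4]),
        (v[1], v[2], v[6], v[5]),
        (v[2], v[3], v[7], v[6]),
        (v[3], v[0], v[4], v[7]),
    ]

    for k in range(n_k - 1):
        for j in range(n_cols):
            for i in range(mp.n_r):
                v = [
                    wall_node(j, i, k),
                    wall_node(j + 1, i, k),
                    wall_node(j + 1, i + 1, k),
                    wall_node(j, i + 1, k),
                    wall_node(j, i, k + 1),
                    wall_node(j + 1, i, k + 1),
                    wall_node(j + 1, i + 1, k + 1),
                    wall_node(j, i + 1, k + 1),
                ]
                cx.add_cell("shell_wall", hex_faces(v))

    # ---- hemispherical caps ----------------------------------------------
    r_mid = 0.5 * (r_i + r_o)
    n_phi = max(3, int(np.ceil(0.5 * np.pi * r_mid / (mp.cap_factor * mp.target_size))))
    # spherical midside projection is safe only while the diagonal-chord
    # sagitta stays well below the wall thickness; otherwise the doubly
    # curved quadratic cap elements can invert, so the caps stay faceted
    c_theta = (angle / n_sec) * r_mid
    c_phi = 0.5 * np.pi * r_mid / n_phi
    sagitta = (c_theta**2 + c_phi**2) / (8.0 * r_mid)
    if sagitta > t_w / (4.0 * mp.n_r):
        for tag in list(cx.surfaces):
            if tag.startswith("cap_"):
                del cx.surfaces[tag]
    phi = np.arange(n_phi + 1) * (0.5 * np.pi / n_phi)

    for end, z_end, zdir, k_wall in (
        ("bottom", 0.0, -1.0, 0),
        ("top", L, +1.0, n_k - 1),
    ):
        region = f"cap_{end}"

        def cap_node(j, i, l, end=end, z_end=z_end, zdir=zdir, k_wall=k_wall):
            if l == 0:
                return wall_node(j, i, k_wall)
            jj = j % n_full if wrap else j
            R = radii_w[i]
            tags = []
            if i == 0:
                tags.append(f"cap_{end}_inner")
            if i == mp.n_r:
                tags.append(f"cap_{end}_outer")
            if l == n_phi:
                tags += ["mirror0", "mirror1", "axis"] if sector else ["axis"]
                return cx.node(("cp", end, i), (0.0, 0.0, z_end + zdir * R), tags)
            if sector and jj == 0:
                tags.append("mirror0")
            if sector and jj == n_sec:
                tags.append("mirror1")
            c, s_ = np.cos(phi[l]), np.sin(phi[l])
            pos = (R * c * cos_t[jj], R * c * sin_t[jj], z_end + zdir * R * s_)
            return cx.node(("c", end, jj, i, l), pos, tags)

        for l in range(n_phi):
            for j in range(n_cols):
                for i in range(mp.n_r):
                    if l < n_phi - 1:
                        v = [
                            cap_node(j, i, l),
                            cap_node(j + 1, i, l),
                            cap_node(j + 1, i + 1, l),
                            cap_node(j, i + 1, l),
                            cap_node(j, i, l + 1),
                            cap_node(j + 1, i, l + 1),
                            cap_node(j + 1, i + 1, l + 1),
                            cap_node(j, i + 1, l + 1),
                        ]
                        cx.add_cell(region, hex_faces(v))
                    else:
                        a0 = cap_node(j, i, l)
                        a1 = cap_node(j + 1, i, l)
                        a2 = cap_node(j + 1, i + 1, l)
                        a3 = cap_node(j, i + 1, l)
                        p0 = cap_node(j, i, n_phi)
                        p1 = cap_node(j, i + 1, n_phi)
                        faces = [
                            (a0, a1, a2, a3),
                            (a0, a1, p0),
                            (a3, a2, p1),
                            (a0, a3, p1, p0),
                            (a1, a2, p1, p0),
                        ]
                        cx.add_cell(region, faces)

    # ---- septa ------------------------------------------------------------
    septum_info = []
    if config.n_septa:
        suture = wrap_on_cylinder(planar, r_i, axial_center=0.0)
        radii_d, divisors_d = plan_rings(r_i, n_full, mp.target_size)
        disc = polar_disc(n_full, radii_d, divisors_d)
        mid = min_curvature_surface(suture, disc=disc, height_field=True)
        normals = mid.vertex_normals()
        flip = normals[:, 2] < 0
        normals[flip] = -normals[flip]  # orient toward +z (apical)
        ring = disc.ring
        jbase = disc.jbase

        if sector:
            in_sector = (jbase >= 0) & (jbase <= n_sec)
            in_sector[disc.apex] = True
            tris = disc.tris[in_sector[disc.tris].all(axis=1)]
        else:
            tris = disc.tris
        used = np.unique(tris.ravel())

        for s, zc in enumerate(config.septum_centres()):
            k_lo = level_tag[f"septum_{s}_lo"]
            k_hi = level_tag[f"septum_{s}_hi"]
            ids = {}
            for sheet, k_wall, sgn in (("b", k_lo, -1.0), ("t", k_hi, +1.0)):
                for v in used:
                    if ring[v] == 0:
                        ids[(sheet, v)] = wall_node(int(jbase[v]), 0, k_wall)
                        continue
                    tags = []
                    if v == disc.apex:
                        tags = ["mirror0", "mirror1", "axis"] if sector else ["axis"]
                    elif sector:
                        if jbase[v] == 0:
                            tags.append("mirror0")
                        if jbase[v] == n_sec:
                            tags.append("mirror1")
                    p = mid.vertices[v] + sgn * h * normals[v]
                    if v == disc.apex:
                        p[0] = p[1] = 0.0
                    elif "mirror0" in tags:
                        p[1] = 0.0  # keep symmetry-plane nodes on their plane
                    elif "mirror1" in tags:
                        nrm = np.array([-np.sin(angle), np.cos(angle), 0.0])
                        p = p - (p @ nrm) * nrm
                    pos = (p[0], p[1], zc + p[2])
                    ids[(sheet, v)] = cx.node(("s", s, sheet, int(v)), pos, tags)
            for tri in tris:
                b0, b1, b2 = (ids[("b", v)] for v in tri)
                t0, t1, t2 = (ids[("t", v)] for v in tri)
                faces = [
                    (b0, b1, b2),
                    (t0, t1, t2),
                    (b0, b1, t1, t0),
                    (b1, b2, t2, t1),
                    (b2, b0, t0, t2),
                ]
                cx.add_cell(f"septum_{s}", faces)
            septum_info.append({"centre_z": float(zc), "k_lo": k_lo, "k_hi": k_hi})

    cx.meta["septa"] = septum_info
    cx.meta["n_phi"] = n_phi
    cx.meta["config_label"] = config.label()
    solid = SolidMesh(
        complex=cx,
        config=config,
        mesh_params=mp,
        sector=sector,
        sector_angle=angle,
    )
    if not solid.is_watertight():
        raise AssemblyError("assembled solid boundary is not watertight")
    return solid


def tet_mesh(
    solid: SolidMesh, target_size: float | None = None, order: int | None = None
) -> FEMesh:
    """Tetrahedralise an assembled solid.

    If ``target_size`` differs from the size the solid was assembled with,
    the solid is rebuilt at the requested resolution first (the constructive
    mesher sizes its cells during assembly).
    """
    mp = solid.mesh_params
    if target_size is not None and not np.isclose(target_size, mp.target_size):
        solid = build_shell(
            solid.config, replace(mp, target_size=target_size), sector=solid.sector
        )
        mp = solid.mesh_params
    mesh = tetrahedralize(solid.complex, order=order if order is not None else mp.order)
    mesh.meta["config"] = solid.config
    mesh.meta["mesh_params"] = mp
    mesh.meta["symmetry_fraction"] = solid.symmetry_fraction
    return mesh
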