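"""Minimum-curvature septal surfaces.

A septum is modelled as the surface spanning its suture line that minimises a
discrete bending (thin-plate / biharmonic) energy, with the boundary clamped
in position on the suture and free in rotation.  The disc-topology
triangulation is a structured polar grid whose rings coarsen toward the
centre (the curvature of real septa decays rapidly away from the suture, so
resolution is concentrated at the boundary).

The same disc mesher is reused by the shell assembly so septa attach to the
inner shell wall node-for-node.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConvergenceError, GeometryError, ParameterError, SelfIntersectionError
from .suture import SutureCurve, max_safe_offset

__all__ = [
    "TriSurface",
    "SolidSeptum",
    "DiscMesh",
    "polar_disc",
    "min_curvature_surface",
    "curvature_map",
    "thicken",
    "cotan_laplacian",
]


# --------------------------------------------------------------------------
# triangulated surface container
# --------------------------------------------------------------------------

@dataclass
class TriSurface:
    """Triangulated surface with one boundary loop."""

    vertices: np.ndarray  # (V, 3) mm
    triangles: np.ndarray  # (T, 3) int
    boundary_ids: np.ndarray  # ordered indices of the boundary loop
    curvature: np.ndarray | None = None  # per-vertex mean curvature, 1/mm
    suture: SutureCurve | None = field(default=None, repr=False)
    energy_history: list = field(default_factory=list, repr=False)

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        e1 = v[t[:, 1]] - v[t[:, 0]]
        e2 = v[t[:, 2]] - v[t[:, 0]]
        return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)

    @property
    def area(self) -> float:
        return float(self.triangle_areas().sum())

    def vertex_normals(self) -> np.ndarray:
        v, t = self.vertices, self.triangles
        fn = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        vn = np.zeros_like(v)
        for k in range(3):
            np.add.at(vn, t[:, k], fn)
        norms = np.linalg.norm(vn, axis=1, keepdims=True)
        return vn / np.where(norms > 1e-14, norms, 1.0)

    def as_trimesh(self):
        import trimesh

        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.triangles, process=False
        )


@dataclass
class SolidSeptum:
    """A septal midsurface thickened into a watertight solid."""

    surface: TriSurface
    thickness: float
    shell_vertices: np.ndarray
    shell_triangles: np.ndarray

    def as_trimesh(self):
        import trimesh

        tm = trimesh.Trimesh(
            vertices=self.shell_vertices, faces=self.shell_triangles, process=False
        )
        trimesh.repair.fix_normals(tm)
        return tm

    @property
    def volume(self) -> float:
        return float(abs(self.as_trimesh().volume))


# --------------------------------------------------------------------------
# structured polar disc
# --------------------------------------------------------------------------

@dataclass
class DiscMesh:
    """Structured polar disc triangulation (unit angular coordinates).

    ``jbase`` indexes angular position in units of the boundary resolution
    (node angle = 2 pi jbase / n_base); ``ring`` indexes radial level, with
    the apex carrying ``ring = len(radii)``.
    """

    n_base: int
    radii: np.ndarray  # ring radii, descending, excluding the apex
    divisors: np.ndarray  # angular subsampling per ring (powers of two)
    ring: np.ndarray  # (V,)
    jbase: np.ndarray  # (V,)
    tris: np.ndarray  # (T, 3)
    apex: int  # node id of the centre vertex

    @property
    def n_vertices(self) -> int:
        return self.ring.size

    def theta(self) -> np.ndarray:
        return 2.0 * np.pi * self.jbase / self.n_base

    def radius(self) -> np.ndarray:
        r = np.zeros(self.n_vertices)
        mask = self.ring < len(self.radii)
        r[mask] = np.asarray(self.radii)[self.ring[mask]]
        return r

    def boundary_ids(self) -> np.ndarray:
        ids = np.where(self.ring == 0)[0]
        return ids[np.argsort(self.jbase[ids])]


def plan_rings(
    r0: float, n_base: int, target_edge: float, min_ring_pts: int = 8
) -> tuple[np.ndarray, np.ndarray]:
    """Choose ring radii and angular divisors for a polar disc.

    The first ring spacing matches the boundary point spacing; spacings grow
    geometrically up to ``target_edge``, and the angular point count halves
    whenever the circumferential spacing falls below half the radial one.
    """
    radii = [r0]
    divisors = [1]
    dr = 2.0 * np.pi * r0 / n_base
    r = r0
    d = 1
    while True:
        dr = min(max(dr * 1.6, 1e-9), target_edge)
        r_next = r - dr
        if r_next < 1.3 * dr:
            break
        npts = n_base // d
        circ_spacing = 2.0 * np.pi * r_next / npts
        while (
            npts % 2 == 0
            and npts // 2 >= min_ring_pts
            and circ_spacing < 0.55 * dr
        ):
            d *= 2
            npts //= 2
            circ_spacing *= 2.0
        radii.append(r_next)
        divisors.append(d)
        r = r_next
    return np.asarray(radii), np.asarray(divisors, dtype=int)


def polar_disc(n_base: int, radii, divisors) -> DiscMesh:
    """Build the triangulation of a full polar disc with coarsening rings."""
    radii = np.asarray(radii, float)
    divisors = np.asarray(divisors, int)
    if n_base % int(divisors.max()) != 0:
        raise ParameterError("n_base must be divisible by every ring divisor")
    ring_list, jbase_list = [], []
    ids = {}  # (ring, jbase) -> node id
    for k, d in enumerate(divisors):
        for j in range(0, n_base, int(d)):
            ids[(k, j)] = len(ring_list)
            ring_list.append(k)
            jbase_list.append(j)
    apex = len(ring_list)
    ring_list.append(len(radii))
    jbase_list.append(0)

    tris = []
    for k in range(len(radii) - 1):
        d0, d1 = int(divisors[k]), int(divisors[k + 1])
        if d1 == d0:
            for j in range(0, n_base, d0):
                jn = (j + d0) % n_base
                a, b = ids[(k, j)], ids[(k, jn)]
                c, e = ids[(k + 1, j)], ids[(k + 1, jn)]
                # split the quad by the diagonal through its smallest node id
                if min(a, e) < min(b, c):
                    tris += [[a, b, e], [a, e, c]]
                else:
                    tris += [[a, b, c], [b, e, c]]
        elif d1 == 2 * d0:
            for j in range(0, n_base, d1):
                jm = (j + d0) % n_base
                jn = (j + d1) % n_base
                A, B, C = ids[(k, j)], ids[(k, jm)], ids[(k, jn)]
                P, Q = ids[(k + 1, j)], ids[(k + 1, jn)]
                tris += [[A, B, P], [B, Q, P], [B, C, Q]]
        else:
            raise ParameterError("ring divisors may only double between rings")
    dK = int(divisors[-1])
    kK = len(radii) - 1
    for j in range(0, n_base, dK):
        jn = (j + dK) % n_base
        tris.append([ids[(kK, j)], ids[(kK, jn)], apex])

    return DiscMesh(
        n_base=n_base,
        radii=radii,
        divisors=divisors,
        ring=np.asarray(ring_list, int),
        jbase=np.asarray(jbase_list, int),
        tris=np.asarray(tris, int),
        apex=apex,
    )


# --------------------------------------------------------------------------
# discrete operators
# --------------------------------------------------------------------------

def cotan_laplacian(vertices: np.ndarray, tris: np.ndarray):
    """Cotangent-weighted Laplacian L and lumped (barycentric) mass M.

    Returns (L, m) with L sparse (V, V), positive semi-definite, and m the
    per-vertex lumped area vector.  Degenerate triangles raise GeometryError.
    """
    v = np.asarray(vertices, float)
    V = v.shape[0]
    t = np.asarray(tris, int)
    i0, i1, i2 = t[:, 0], t[:, 1], t[:, 2]
    e0 = v[i2] - v[i1]
    e1 = v[i0] - v[i2]
    e2 = v[i1] - v[i0]
    area2 = np.linalg.norm(np.cross(e2, -e1), axis=1)  # 2 * area
    if np.any(area2 <= 1e-14):
        raise GeometryError("degenerate (zero-area) triangle in surface")
    # cotangents at each corner
    cot0 = np.einsum("ij,ij->i", -e1, e2) / area2
    cot1 = np.einsum("ij,ij->i", -e2, e0) / area2
    cot2 = np.einsum("ij,ij->i", -e0, e1) / area2
    I = np.concatenate([i1, i2, i2, i0, i0, i1])
    J = np.concatenate([i2, i1, i0, i2, i1, i0])
    W = 0.5 * np.concatenate([cot0, cot0, cot1, cot1, cot2, cot2])
    L = sp.coo_matrix((-W, (I, J)), shape=(V, V)).tocsr()
    L = L - sp.diags(np.asarray(L.sum(axis=1)).ravel())
    m = np.zeros(V)
    a3 = area2 / 6.0  # triangle area / 3
    for idx in (i0, i1, i2):
        np.add.at(m, idx, a3)
    return L, m


def _bilaplacian_solve(L, m, free, fixed, coords_fixed_vals, coords_init):
    """Solve K x = 0 with K = L^T M^-1 L, position-clamped boundary."""
    Minv = sp.diags(1.0 / m)
    K = (L.T @ Minv @ L).tocsr()
    Kff = K[free][:, free].tocsc()
    Kfb = K[free][:, fixed]
    lu = spla.splu(Kff)
    out = coords_init.copy()
    for c in range(coords_init.shape[1]):
        rhs = -Kfb @ coords_fixed_vals[:, c]
        out[free, c] = lu.solve(rhs)
    energy = float(sum(out[:, c] @ (K @ out[:, c]) for c in range(out.shape[1])))
    return out, energy


def min_curvature_surface(
    boundary: SutureCurve,
    target_edge_length: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    height_field: bool = False,
    disc: DiscMesh | None = None,
) -> TriSurface:
    """Minimum-curvature surface spanning a closed suture curve.

    Interior vertices minimise the discrete thin-plate (biharmonic) energy
    ``sum_c x_c^T L^T M^-1 L x_c`` with the boundary clamped in position on
    the suture and free in rotation; the cotangent Laplacian is rebuilt from
    the current geometry and the solve repeated until the relative energy
    change falls below ``tol``.  The reported energy never increases between
    iterations.

    With ``height_field=True`` only the axial coordinate is solved (the
    in-plane polar layout stays fixed); this variant is deterministic in one
    solve and is what the shell assembly uses.
    """
    if not boundary.is_simple():
        raise GeometryError("boundary suture is not simple")
    r0 = boundary.cylinder_radius
    if target_edge_length is None:
        target_edge_length = 0.15 * r0
    if target_edge_length <= 0:
        raise ParameterError("target_edge_length must be positive")

    if disc is None:
        n_base = int(round(2.0 * np.pi * r0 / target_edge_length))
        n_base = max(16, 8 * int(np.ceil(n_base / 8)))
        radii, divisors = plan_rings(r0, n_base, target_edge_length)
        disc = polar_disc(n_base, radii, divisors)

    theta = disc.theta()
    rad = disc.radius()
    zb = boundary.z_of_theta(theta)  # boundary profile sampled everywhere
    verts = np.column_stack([rad * np.cos(theta), rad * np.sin(theta), np.zeros_like(rad)])
    bnd = disc.boundary_ids()
    is_b = np.zeros(disc.n_vertices, bool)
    is_b[bnd] = True
    verts[bnd, 2] = zb[bnd]
    free = np.where(~is_b)[0]
    fixed = np.where(is_b)[0]

    # harmonic initialisation of the axial coordinate
    L, m = cotan_laplacian(
        np.column_stack([verts[:, 0], verts[:, 1], np.zeros(disc.n_vertices)]),
        disc.tris,
    )
    Lff = L[free][:, free].tocsc()
    Lfb = L[free][:, fixed]
    verts[free, 2] = spla.splu(Lff).solve(-Lfb @ verts[fixed, 2])

    energies = []
    prev = np.inf
    for it in range(max_iter):
        L, m = cotan_laplacian(verts, disc.tris)
        cols = [2] if height_field else [0, 1, 2]
        new, energy = _bilaplacian_solve(
            L, m, free, fixed, verts[fixed][:, cols], verts[:, cols]
        )
        cand = verts.copy()
        cand[:, cols] = new
        if energies and energy > energies[-1] * (1.0 + 1e-12):
            break  # keep the monotone iterate
        verts = cand
        energies.append(energy)
        if height_field:
            break  # linear in z: one solve is exact
        if prev < np.inf and abs(prev - energy) <= tol * max(abs(prev), 1e-30):
            break
        prev = energy
    else:
        raise ConvergenceError(
            "biharmonic surface solver did not converge",
            diagnostics={"energies": energies, "tol": tol, "max_iter": max_iter},
        )

    surf = TriSurface(
        vertices=verts,
        triangles=disc.tris.copy(),
        boundary_ids=bnd,
        suture=boundary,
        energy_history=energies,
    )
    return surf


def curvature_map(surface: TriSurface) -> np.ndarray:
    """Per-vertex discrete mean curvature (1/mm); boundary vertices are NaN.

    Uses the cotangent Laplacian: the mean-curvature normal is
    ``(M^-1 L P) / 2``; the signed magnitude (positive toward the vertex
    normal) is stored on ``surface.curvature`` and returned.
    """
    L, m = cotan_laplacian(surface.vertices, surface.triangles)
    hn = (L @ surface.vertices) / (2.0 * m[:, None])
    n = surface.vertex_normals()
    h = np.linalg.norm(hn, axis=1) * np.sign(np.einsum("ij,ij->i", hn, n))
    h[surface.boundary_ids] = np.nan
    surface.curvature = h
    return h


def thicken(
    surface: TriSurface, thickness: float, check_offset: bool = True
) -> SolidSeptum:
    """Thicken a midsurface into a watertight solid septum.

    The midsurface is offset by half the thickness along both vertex-normal
    directions and the rim is stitched along the boundary loop.  If the
    surface carries its suture, the thickness is checked against the largest
    self-intersection-free offset of the suture (thin, highly frilled sutures
    only admit thin septa).
    """
    if thickness <= 0:
        raise ParameterError("thickness must be positive")
    if check_offset and surface.suture is not None:
        limit = 2.0 * max_safe_offset(surface.suture)
        if thickness > limit:
            raise SelfIntersectionError(
                f"septal thickness {thickness:.4g} mm exceeds the "
                f"self-intersection limit {limit:.4g} mm of this suture"
            )
    v = surface.vertices
    n = surface.vertex_normals()
    # orient the offset direction toward +z (apical) on average
    if n[:, 2].sum() < 0:
        n = -n
    top = v + 0.5 * thickness * n
    bot = v - 0.5 * thickness * n
    V = v.shape[0]
    verts = np.vstack([top, bot])
    t = surface.triangles
    tris = [t, t[:, ::-1] + V]
    b = surface.boundary_ids
    nb = b.size
    for i in range(nb):
        a, c = b[i], b[(i + 1) % nb]
        # rim quad (top a, top c, bottom c, bottom a)
        tris.append(np.array([[a, c, c + V], [a, c + V, a + V]]))
    shell_tris = np.vstack(tris)
    return SolidSeptum(
        surface=surface,
        thickness=thickness,
        shell_vertices=verts,
        shell_triangles=shell_tris,
    )
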