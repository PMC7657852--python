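"""Linear isotropic elasticity on tetrahedral meshes.

Displacement-based FEM with linear (4-node) or quadratic (10-node)
tetrahedra.  External hydrostatic pressure is applied as a dead traction
``-P n`` on the (curved, isoparametric) external surface facets; rigid-body
modes are removed either by mirror-symmetry conditions on sector models or
by a 3-2-1 point constraint scheme on full models.  The sparse symmetric
positive-definite system is solved by direct factorisation.

Unit system: mm - MPa - N; displacements in mm, stresses in MPa, energies in
mJ (N mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .assembly import MaterialParams
from .errors import ConstraintError, MeshQualityError, ParameterError
from .mesh import FEMesh

__all__ = [
    "PressureLoad",
    "ElasticSolution",
    "Constraints",
    "solve",
    "solve_pressure_series",
    "constrain_rigid_body",
    "symmetry_constraints",
    "recover_nodal_stress",
]

# Voigt component order used throughout: xx, yy, zz, xy, yz, zx
VOIGT = ((0, 0), (1, 1), (2, 2), (0, 1), (1, 2), (2, 0))


@dataclass
class PressureLoad:
    """Uniform pressure on a facet set (default: the external surface)."""

    magnitude: float  # MPa
    facets: np.ndarray | None = None  # (F, 3|6) node ids, outward orientation

    def __post_init__(self):
        if self.magnitude < 0:
            raise ParameterError("pressure magnitude must be >= 0")


@dataclass
class Constraints:
    """Homogeneous constraints: fixed dofs plus rotated-frame normal dofs."""

    fixed: list  # list of (node, component)
    oblique: list = field(default_factory=list)  # (node, unit normal) -> u.n = 0

    @property
    def n_scalar(self) -> int:
        return len(self.fixed) + len(self.oblique)


@dataclass
class ElasticSolution:
    """Displacements, stresses and diagnostics of one load case."""

    mesh: FEMesh
    displacements: np.ndarray  # (N, 3) mm
    element_stress: np.ndarray  # (E, nodes/elem, 6) MPa, Voigt order
    strain_energy: float  # mJ
    pressure: float
    diagnostics: dict = field(default_factory=dict)
    _nodal_stress: np.ndarray | None = None

    @property
    def nodal_stress(self) -> np.ndarray:
        if self._nodal_stress is None:
            self._nodal_stress = recover_nodal_stress(self, self.mesh)
        return self._nodal_stress

    def scaled(self, pressure: float) -> "ElasticSolution":
        """Exact solution at another pressure (linearity)."""
        fac = pressure / self.pressure
        out = ElasticSolution(
            mesh=self.mesh,
            displacements=self.displacements * fac,
            element_stress=self.element_stress * fac,
            strain_energy=self.strain_energy * fac**2,
            pressure=pressure,
            diagnostics=dict(self.diagnostics, scaled_from=self.pressure),
        )
        if self._nodal_stress is not None:
            out._nodal_stress = self._nodal_stress * fac
        return out


# --------------------------------------------------------------------------
# element tables
# --------------------------------------------------------------------------

def _tet10_dshape(x: np.ndarray) -> np.ndarray:
    """d N / d xi for the 10-node tet at local point x = (xi, eta, zeta)."""
    xi, eta, zeta = x
    l0 = 1.0 - xi - eta - zeta
    lam = np.array([l0, xi, eta, zeta])
    dlam = np.array([[-1.0, -1.0, -1.0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    d = np.zeros((10, 3))
    for i in range(4):
        d[i] = (4.0 * lam[i] - 1.0) * dlam[i]
    edges = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
    for col, (i, j) in enumerate(edges, start=4):
        d[col] = 4.0 * (lam[i] * dlam[j] + lam[j] * dlam[i])
    return d


def _tet4_dshape(_x=None) -> np.ndarray:
    return np.array([[-1.0, -1.0, -1.0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])


_TET10_NODE_XI = np.array(
    [
        [0, 0, 0],
        [1, 0, 0],
        [0, 1, 0],
        [0, 0, 1],
        [0.5, 0, 0],
        [0, 0.5, 0],
        [0, 0, 0.5],
        [0.5, 0.5, 0],
        [0.5, 0, 0.5],
        [0, 0.5, 0.5],
    ],
    dtype=float,
)

_A, _B = 0.5854101966249685, 0.1381966011250105
_TET_GAUSS = np.array(
    [[_B, _B, _B], [_A, _B, _B], [_B, _A, _B], [_B, _B, _A]]
)
_TET_W = np.full(4, 1.0 / 24.0)  # weights sum to the unit-tet volume 1/6


def _tri_shapes(order: int, u: float, v: float):
    z0, z1, z2 = 1.0 - u - v, u, v
    if order == 1:
        n = np.array([z0, z1, z2])
        dn = np.array([[-1.0, -1.0], [1, 0], [0, 1]])
        return n, dn
    n = np.array(
        [
            z0 * (2 * z0 - 1),
            z1 * (2 * z1 - 1),
            z2 * (2 * z2 - 1),
            4 * z0 * z1,
            4 * z1 * z2,
            4 * z2 * z0,
        ]
    )
    dz = np.array([[-1.0, -1.0], [1, 0], [0, 1]])
    dn = np.zeros((6, 2))
    for i in range(3):
        dn[i] = (4 * (z0, z1, z2)[i] - 1) * dz[i]
    pairs = ((0, 1), (1, 2), (2, 0))
    zs = (z0, z1, z2)
    for col, (i, j) in enumerate(pairs, start=3):
        dn[col] = 4 * (zs[i] * dz[j] + zs[j] * dz[i])
    return n, dn


_TRI_GAUSS = [(1 / 6, 1 / 6), (2 / 3, 1 / 6), (1 / 6, 2 / 3)]
_TRI_W = [1 / 6, 1 / 6, 1 / 6]


# --------------------------------------------------------------------------
# assembly
# --------------------------------------------------------------------------

def assemble_stiffness(mesh: FEMesh, material: MaterialParams) -> sp.csr_matrix:
    """Assemble the global stiffness matrix (3 dofs per node)."""
    lam, mu = material.lame
    conn = mesh.conn
    n_en = conn.shape[1]
    ndof = 3 * mesh.n_nodes
    dshapes = (
        [_tet4_dshape()]
        if mesh.order == 1
        else [_tet10_dshape(x) for x in _TET_GAUSS]
    )
    weights = [1.0 / 6.0] if mesh.order == 1 else list(_TET_W)

    E = conn.shape[0]
    chunk = max(1, int(4e6 // (n_en * n_en)))
    rows_all, cols_all, vals_all = [], [], []
    eye = np.eye(3)
    for start in range(0, E, chunk):
        c = conn[start : start + chunk]
        m = c.shape[0]
        X = mesh.nodes[c]  # (m, n_en, 3)
        Ke = np.zeros((m, n_en * 3, n_en * 3))
        for dN, w in zip(dshapes, weights):
            J = np.einsum("ak,eal->ekl", dN, X)  # dx_l / dxi_k
            detJ = np.linalg.det(J)
            if np.any(detJ <= 0):
                raise MeshQualityError("non-positive Jacobian during assembly")
            Jinv = np.linalg.inv(J)
            G = np.einsum("ak,elk->eal", dN, Jinv)  # dN_a / dx_l
            gg = np.einsum("eai,ebj->eaibj", G, G)
            dot = np.einsum("eal,ebl->eab", G, G)
            # lam * G_{a,i} G_{b,j} + mu * G_{a,j} G_{b,i} + mu * d_ij (Ga.Gb)
            kb = lam * gg + mu * np.transpose(gg, (0, 1, 4, 3, 2))
            kb += mu * np.einsum("eab,ij->eaibj", dot, eye)
            Ke += (w * detJ)[:, None, None] * kb.reshape(m, n_en * 3, n_en * 3)
        dof = (3 * c[:, :, None] + np.arange(3)[None, None, :]).reshape(m, n_en * 3)
        rows_all.append(np.repeat(dof, n_en * 3, axis=1).ravel())
        cols_all.append(np.tile(dof, (1, n_en * 3)).ravel())
        vals_all.append(Ke.ravel())
    K = sp.coo_matrix(
        (
            np.concatenate(vals_all),
            (np.concatenate(rows_all), np.concatenate(cols_all)),
        ),
        shape=(ndof, ndof),
    ).tocsr()
    return K


def pressure_forces(mesh: FEMesh, load: PressureLoad) -> np.ndarray:
    """Consistent nodal forces of a uniform pressure (traction -P n)."""
    facets = load.facets if load.facets is not None else mesh.external_facets
    f = np.zeros((mesh.n_nodes, 3))
    if facets is None or len(facets) == 0 or load.magnitude == 0.0:
        return f
    facets = np.asarray(facets)
    order = 2 if facets.shape[1] == 6 else 1
    X = mesh.nodes[facets]  # (F, 3|6, 3)
    for (u, v), w in zip(_TRI_GAUSS, _TRI_W):
        n, dn = _tri_shapes(order, u, v)
        du = np.einsum("a,fal->fl", dn[:, 0], X)
        dv = np.einsum("a,fal->fl", dn[:, 1], X)
        nvec = np.cross(du, dv)  # outward-directed area vector
        contrib = -load.magnitude * w * np.einsum("a,fl->fal", n, nvec)
        np.add.at(f, facets, contrib)
    return f


# --------------------------------------------------------------------------
# constraints
# --------------------------------------------------------------------------

def symmetry_constraints(mesh: FEMesh) -> Constraints:
    """Mirror-plane conditions for a sector model, plus one axial anchor."""
    alpha = mesh.meta.get("sector_angle")
    if alpha is None or mesh.meta.get("symmetry_fraction", 1.0) >= 1.0:
        raise ConstraintError("mesh is not a symmetric sector model")
    m0 = set(mesh.set("mirror0").tolist())
    m1 = set(mesh.set("mirror1").tolist())
    both = m0 & m1
    fixed = []
    oblique = []
    for n in sorted(both):  # axis nodes: only axial motion allowed
        fixed += [(n, 0), (n, 1)]
    for n in sorted(m0 - both):  # plane theta=0 -> normal is +y
        fixed.append((n, 1))
    n1 = np.array([-np.sin(alpha), np.cos(alpha), 0.0])
    for n in sorted(m1 - both):
        oblique.append((n, n1))
    # anchor the remaining axial translation at the lowest axis node
    axis = mesh.set("axis")
    if axis.size:
        anchor = int(axis[np.argmin(mesh.nodes[axis, 2])])
    else:
        anchor = int(np.argmin(mesh.nodes[:, 2]))
        fixed += [(anchor, 0), (anchor, 1)]
    fixed.append((anchor, 2))
    return Constraints(fixed=fixed, oblique=oblique)


def constrain_rigid_body(mesh: FEMesh) -> Constraints:
    """3-2-1 point constraints removing the six rigid-body modes.

    Three well-separated, non-collinear nodes: all three components are fixed
    at the first, two at the second (perpendicular to the separation), one at
    the third (perpendicular to the constraint plane).  For a self-equilibrated
    load (closed pressure surface) the reactions vanish.
    """
    pts = mesh.nodes
    if pts.shape[0] < 3:
        raise ConstraintError("mesh has fewer than 3 nodes")
    n1 = int(np.argmin(pts.sum(axis=1)))
    d = np.linalg.norm(pts - pts[n1], axis=1)
    n2 = int(np.argmax(d))
    u = pts[n2] - pts[n1]
    u = u / np.linalg.norm(u)
    # distance from the n1-n2 line
    rel = pts - pts[n1]
    perp = rel - np.outer(rel @ u, u)
    n3 = int(np.argmax(np.linalg.norm(perp, axis=1)))
    if np.linalg.norm(perp[n3]) < 1e-9:
        raise ConstraintError("could not find three non-collinear nodes")
    drop = int(np.argmax(np.abs(u)))  # direction along n1-n2: leave free
    comps2 = [c for c in range(3) if c != drop]
    w = np.cross(u, perp[n3] / np.linalg.norm(perp[n3]))
    comp3 = int(np.argmax(np.abs(w)))
    fixed = [(n1, 0), (n1, 1), (n1, 2)]
    fixed += [(n2, c) for c in comps2]
    fixed.append((n3, comp3))
    return Constraints(fixed=fixed)


def _constraint_operators(mesh: FEMesh, constraints: Constraints):
    """Return (T, free_mask): u = T u', with fixed entries of u' masked out."""
    ndof = 3 * mesh.n_nodes
    free = np.ones(ndof, bool)
    for n, c in constraints.fixed:
        free[3 * n + c] = False
    if not constraints.oblique:
        return None, free
    blocks_i, blocks_j, blocks_v = [], [], []
    touched = np.zeros(mesh.n_nodes, bool)
    for n, nrm in constraints.oblique:
        nrm = np.asarray(nrm, float)
        nrm = nrm / np.linalg.norm(nrm)
        # orthonormal in-plane directions
        a = np.cross(nrm, [0.0, 0.0, 1.0])
        if np.linalg.norm(a) < 1e-8:
            a = np.cross(nrm, [1.0, 0.0, 0.0])
        a /= np.linalg.norm(a)
        b = np.cross(nrm, a)
        R = np.column_stack([a, b, nrm])  # local dofs: (t1, t2, normal)
        for i in range(3):
            for j in range(3):
                blocks_i.append(3 * n + i)
                blocks_j.append(3 * n + j)
                blocks_v.append(R[i, j])
        touched[n] = True
    # identity elsewhere
    ident = np.where(~np.repeat(touched, 3))[0]
    blocks_i += ident.tolist()
    blocks_j += ident.tolist()
    blocks_v += [1.0] * ident.size
    T = sp.coo_matrix((blocks_v, (blocks_i, blocks_j)), shape=(ndof, ndof)).tocsr()
    for n, _ in constraints.oblique:
        free[3 * n + 2] = False  # third local dof = normal displacement
    return T, free


# --------------------------------------------------------------------------
# solve and stress recovery
# --------------------------------------------------------------------------

def _element_stress(mesh: FEMesh, u: np.ndarray, material: MaterialParams):
    """Stress (Voigt) evaluated at every element node."""
    lam, mu = material.lame
    conn = mesh.conn
    n_en = conn.shape[1]
    X = mesh.nodes[conn]
    U = u.reshape(-1, 3)[conn]  # (E, n_en, 3)
    pts = _TET10_NODE_XI[:n_en] if mesh.order == 2 else _TET10_NODE_XI[:4]
    out = np.empty((conn.shape[0], n_en, 6))
    for p, x in enumerate(pts):
        dN = _tet10_dshape(x) if mesh.order == 2 else _tet4_dshape()
        J = np.einsum("ak,eal->ekl", dN, X)
        Jinv = np.linalg.inv(J)
        G = np.einsum("ak,elk->eal", dN, Jinv)
        grad = np.einsum("eal,eam->elm", G, U)  # du_m / dx_l
        eps = 0.5 * (grad + np.transpose(grad, (0, 2, 1)))
        tr = np.trace(eps, axis1=1, axis2=2)
        sig = 2.0 * mu * eps
        sig[:, 0, 0] += lam * tr
        sig[:, 1, 1] += lam * tr
        sig[:, 2, 2] += lam * tr
        for k, (i, j) in enumerate(VOIGT):
            out[:, p, k] = sig[:, i, j]
    return out


def recover_nodal_stress(solution: ElasticSolution, mesh: FEMesh) -> np.ndarray:
    """Volume-weighted average of element nodal stresses onto mesh nodes."""
    conn = mesh.conn
    vols = mesh.volumes()
    acc = np.zeros((mesh.n_nodes, 6))
    wgt = np.zeros(mesh.n_nodes)
    w_el = vols[:, None] * np.ones((1, conn.shape[1]))
    np.add.at(acc, conn, solution.element_stress * w_el[:, :, None])
    np.add.at(wgt, conn, w_el)
    wgt[wgt == 0] = 1.0
    return acc / wgt[:, None]


def solve(
    mesh: FEMesh,
    material: MaterialParams | None = None,
    load: PressureLoad | None = None,
    constraints: Constraints | None = None,
) -> ElasticSolution:
    """Solve one pressure load case on a meshed model."""
    sols = solve_pressure_series(mesh, material, [None if load is None else load],
                                 constraints)
    return sols[0]


def solve_pressure_series(
    mesh: FEMesh,
    material: MaterialParams | None = None,
    loads=None,
    constraints: Constraints | None = None,
) -> list[ElasticSolution]:
    """Factorise once and solve a series of pressure loads.

    ``loads`` may contain PressureLoad objects or bare magnitudes; ``None``
    entries take the pressure from the mesh's model config.
    """
    cfg = mesh.meta.get("config")
    if material is None:
        material = cfg.material if cfg is not None else MaterialParams()
    if loads is None:
        loads = [None]
    load_objs = []
    for ld in loads:
        if ld is None:
            load_objs.append(PressureLoad(cfg.pressure if cfg is not None else 1.0))
        elif isinstance(ld, PressureLoad):
            load_objs.append(ld)
        else:
            load_objs.append(PressureLoad(float(ld)))

    if constraints is None:
        if mesh.meta.get("symmetry_fraction", 1.0) < 1.0:
            constraints = symmetry_constraints(mesh)
        else:
            constraints = constrain_rigid_body(mesh)

    K = assemble_stiffness(mesh, material)
    T, free = _constraint_operators(mesh, constraints)
    Kc = K if T is None else (T.T @ K @ T).tocsr()
    Kff = Kc[free][:, free].tocsc()
    try:
        lu = spla.splu(Kff, permc_spec="MMD_AT_PLUS_A")
    except RuntimeError as exc:  # pragma: no cover
        raise MeshQualityError(f"factorisation failed: {exc}") from exc

    out = []
    for ld in load_objs:
        f = pressure_forces(mesh, ld).ravel()
        fc = f if T is None else T.T @ f
        u_red = lu.solve(fc[free])
        uc = np.zeros(3 * mesh.n_nodes)
        uc[free] = u_red
        u = uc if T is None else T @ uc
        residual = K @ u - f
        react = np.abs(residual[~free]).sum() if (~free).any() else 0.0
        traction_norm = np.abs(f).sum()
        energy = 0.5 * float(f @ u)
        stress = _element_stress(mesh, u, material)
        sol = ElasticSolution(
            mesh=mesh,
            displacements=u.reshape(-1, 3),
            element_stress=stress,
            strain_energy=energy,
            pressure=ld.magnitude,
            diagnostics={
                "n_dof": int(free.sum()),
                "reaction_abs": float(react),
                "traction_abs": float(traction_norm),
                "residual_inf": float(np.abs(residual[free]).max())
                if free.any()
                else 0.0,
                "material": material,
            },
        )
        out.append(sol)
    return out
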