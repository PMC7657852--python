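"""Elasticity solver benchmarks: hydrostatic state, Lame thick wall,
linearity, equilibrium and stress recovery."""

import numpy as np
import pytest

from septamech.analysis import to_cylindrical
from septamech.assembly import MaterialParams
from septamech.errors import ParameterError
from septamech.experiments import make_fixture, _cube_mesh
from septamech.fem import (
    Constraints,
    PressureLoad,
    constrain_rigid_body,
    recover_nodal_stress,
    solve,
    solve_pressure_series,
)

P = 2.0


@pytest.fixture(scope="module", params=[1, 2], ids=["tet4", "tet10"])
def cube_case(request):
    mesh = _cube_mesh(2, order=request.param)
    sol = solve(mesh, MaterialParams(), PressureLoad(P, mesh.external_facets))
    return mesh, sol


class TestHydrostaticCube:
    def test_uniform_state_is_exact(self, cube_case):
        _, sol = cube_case
        target = np.array([-P, -P, -P, 0.0, 0.0, 0.0])
        assert np.abs(sol.element_stress - target).max() < 1e-6

    def test_reactions_vanish_for_closed_pressure(self, cube_case):
        _, sol = cube_case
        ratio = sol.diagnostics["reaction_abs"] / sol.diagnostics["traction_abs"]
        assert ratio < 1e-6

    def test_nodal_recovery_reproduces_constant_field(self, cube_case):
        mesh, sol = cube_case
        nodal = recover_nodal_stress(sol, mesh)
        target = np.array([-P, -P, -P, 0.0, 0.0, 0.0])
        assert np.abs(nodal - target).max() < 1e-6

    def test_strain_energy_closed_form(self, cube_case):
        # U = 1/2 sigma:eps * V = 3 P^2 (1 - 2 nu) / (2 E) for a unit cube
        _, sol = cube_case
        m = MaterialParams()
        expected = 3 * P**2 * (1 - 2 * m.poisson_ratio) / (2 * m.youngs_modulus)
        assert sol.strain_energy == pytest.approx(expected, rel=1e-9)

    def test_constraint_placement_does_not_change_stress(self, cube_case):
        mesh, sol = cube_case
        # a different valid 3-2-1 triple: use three other corner nodes
        c = np.array([1.0, 1.0, 1.0])
        n1 = int(np.argmin(np.linalg.norm(mesh.nodes - c, axis=1)))
        n2 = int(np.argmax(np.abs(mesh.nodes[:, 0] - mesh.nodes[n1, 0])))
        n3 = int(np.argmax(np.abs(mesh.nodes[:, 1] - mesh.nodes[n1, 1])))
        alt = Constraints(
            fixed=[(n1, 0), (n1, 1), (n1, 2), (n2, 1), (n2, 2), (n3, 2)]
        )
        sol2 = solve(mesh, MaterialParams(), PressureLoad(P, mesh.external_facets), alt)
        rel = np.abs(sol2.element_stress - sol.element_stress).max() / P
        assert rel < 1e-3


class TestLinearity:
    def test_doubling_pressure_doubles_fields(self):
        mesh = _cube_mesh(2, order=2)
        s1, s2 = solve_pressure_series(
            mesh,
            MaterialParams(),
            [PressureLoad(P, mesh.external_facets),
             PressureLoad(2 * P, mesh.external_facets)],
        )
        assert np.allclose(2 * s1.displacements, s2.displacements, atol=1e-14)
        assert np.allclose(2 * s1.element_stress, s2.element_stress, atol=1e-10)
        assert s2.strain_energy == pytest.approx(4 * s1.strain_energy, rel=1e-9)

    def test_scaled_solution_matches_direct_solve(self):
        mesh = _cube_mesh(2, order=2)
        s1 = solve(mesh, MaterialParams(), PressureLoad(P, mesh.external_facets))
        s3 = s1.scaled(3.0)
        assert s3.pressure == 3.0
        assert np.allclose(s3.displacements, s1.displacements * 1.5)
        assert s3.strain_energy == pytest.approx(s1.strain_energy * 2.25)


class TestLameThickWall:
    def test_inner_wall_hoop_matches_closed_form(self):
        fx = make_fixture("lame_cylinder", pressure=P)
        sol = fx.solve()
        ids = fx.mesh.set("inner_cyl")
        cyl = to_cylindrical(sol.nodal_stress[ids], fx.mesh.nodes[ids])
        r = np.hypot(fx.mesh.nodes[ids, 0], fx.mesh.nodes[ids, 1])
        truth = fx.truth["hoop_profile"](r)
        assert abs(cyl.tangential.mean() / truth.mean() - 1) < 0.02

    def test_radial_stress_boundary_values(self):
        fx = make_fixture("lame_cylinder", pressure=P)
        sol = fx.solve()
        outer = fx.mesh.set("outer_cyl")
        cyl = to_cylindrical(sol.nodal_stress[outer], fx.mesh.nodes[outer])
        # sigma_rr -> -P at the loaded outer face
        assert cyl.radial.mean() == pytest.approx(-P, rel=0.05)


def test_rigid_body_constraint_count():
    mesh = _cube_mesh(2, order=1)
    c = constrain_rigid_body(mesh)
    assert c.n_scalar == 6


def test_negative_pressure_rejected():
    with pytest.raises(ParameterError):
        PressureLoad(-1.0)


def test_quadratic_beats_linear_on_thin_shell():
    """Order-2 elements reach the membrane state at a coarse mesh where
    order-1 elements still lock."""
    from septamech.assembly import MeshParams, ModelConfig, build_shell, tet_mesh
    from septamech.analysis import validation_error

    cfg = ModelConfig(n_septa=0)
    errs = {}
    for order in (1, 2):
        mesh = tet_mesh(build_shell(cfg, MeshParams(order=order)))
        sol = solve(mesh, cfg.material, PressureLoad(P))
        errs[order] = validation_error(sol, cfg)
    assert errs[2] < errs[1]
    assert errs[2] < 4.0
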