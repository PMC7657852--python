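"""Shell assembly and tetrahedral meshing: watertightness, conformity,
volume conservation, region labelling."""

import numpy as np
import pytest

from septamech.assembly import (
    MeshParams,
    ModelConfig,
    build_shell,
    tet_mesh,
)
from septamech.errors import ParameterError
from septamech.suture import SutureSpec


@pytest.fixture(scope="module")
def sexilobate_solid():
    return build_shell(ModelConfig())


@pytest.fixture(scope="module")
def sexilobate_mesh(sexilobate_solid):
    return tet_mesh(sexilobate_solid)


class TestModelConfig:
    @pytest.mark.parametrize(
        "spacing,n_septa", [(5.0, 5), (10.0, 3), (20.0, 2)]
    )
    def test_spacing_suite_geometry(self, spacing, n_septa):
        cfg = ModelConfig(septal_spacing=spacing, n_septa=n_septa)
        centres = cfg.septum_centres()
        assert centres.size == n_septa
        assert np.allclose(np.diff(centres), spacing)
        # septal band is centred on midlength
        assert centres.mean() == pytest.approx(cfg.length / 2)

    @pytest.mark.parametrize("t,r_o", [(0.5, 9.61), (0.1, 9.21)])
    def test_outer_radius(self, t, r_o):
        assert ModelConfig(shell_thickness=t).outer_radius == pytest.approx(
            9.11 + t
        )
        assert ModelConfig(shell_thickness=t).outer_radius == pytest.approx(r_o)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ParameterError):
            ModelConfig(shell_thickness=-1.0)
        with pytest.raises(ParameterError):
            ModelConfig(septal_spacing=0.3, septal_thickness=0.4)


class TestBuildShell:
    def test_assembled_solid_is_watertight(self, sexilobate_solid):
        assert sexilobate_solid.is_watertight()

    def test_empty_phragmocone_is_valid(self):
        solid = build_shell(ModelConfig(n_septa=0))
        assert solid.is_watertight()
        mesh = tet_mesh(solid)
        assert set(mesh.region_names) == {"shell_wall", "cap_bottom", "cap_top"}

    def test_septa_regions_present(self, sexilobate_mesh):
        septa = [r for r in sexilobate_mesh.region_names if r.startswith("septum")]
        assert len(septa) == 5

    def test_full_circle_mode(self):
        cfg = ModelConfig(n_septa=1, suture=SutureSpec(family="lobate", n_lobes=3))
        solid = build_shell(cfg, sector=False)
        assert solid.symmetry_fraction == pytest.approx(1.0)
        assert solid.is_watertight()


class TestTetMesh:
    def test_quadratic_elements_have_ten_nodes(self, sexilobate_mesh):
        assert sexilobate_mesh.order == 2
        assert sexilobate_mesh.conn.shape[1] == 10

    def test_all_volumes_positive(self, sexilobate_mesh):
        assert sexilobate_mesh.volumes().min() > 0

    def test_septum_wall_junction_shares_nodes(self, sexilobate_mesh):
        wall = set(sexilobate_mesh.nodes_of_region("shell_wall").tolist())
        sep = set(sexilobate_mesh.nodes_of_region("septum_2").tolist())
        shared = wall & sep
        assert shared  # conformal attachment, no duplicated interface nodes
        pts = sexilobate_mesh.nodes[sorted(shared)]
        r = np.hypot(pts[:, 0], pts[:, 1])
        assert np.abs(r - 9.11).max() < 1e-6

    def test_volume_conservation_no_septa(self):
        cfg = ModelConfig(n_septa=0)
        mesh = tet_mesh(build_shell(cfg))
        r_i, r_o, L = cfg.inner_radius, cfg.outer_radius, cfg.length
        exact = (
            np.pi * (r_o**2 - r_i**2) * L
            + 2.0 * (2.0 / 3.0) * np.pi * (r_o**3 - r_i**3)
        ) * mesh.meta["symmetry_fraction"]
        assert mesh.quality["total_volume"] == pytest.approx(exact, rel=0.01)

    def test_external_facets_cover_outer_surface_only(self, sexilobate_mesh):
        facets = sexilobate_mesh.external_facets
        corners = np.unique(facets[:, :3].ravel())
        pts = sexilobate_mesh.nodes[corners]
        r = np.hypot(pts[:, 0], pts[:, 1])
        L = sexilobate_mesh.meta["length"]
        on_cyl = np.abs(r - 9.61) < 1e-6
        below = pts[:, 2] < 0
        above = pts[:, 2] > L
        d_bot = np.linalg.norm(pts - [0, 0, 0], axis=1)
        d_top = np.linalg.norm(pts - [0, 0, L], axis=1)
        on_cap = (np.abs(d_bot - 9.61) < 1e-6) | (np.abs(d_top - 9.61) < 1e-6)
        assert np.all(on_cyl | (on_cap & (below | above)))

    def test_rebuild_at_other_target_size(self, sexilobate_solid):
        coarse = tet_mesh(sexilobate_solid)
        finer = tet_mesh(sexilobate_solid, target_size=0.9)
        assert finer.n_elements > coarse.n_elements
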