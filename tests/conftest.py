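import numpy as np
import pytest

from septamech.assembly import MeshParams, ModelConfig, build_shell, tet_mesh
from septamech.fem import solve_pressure_series


@pytest.fixture(scope="session")
def sexilobate_solution():
    """Coarse sexilobate reference model (5 septa, 0.5 mm wall) at 2 MPa."""
    cfg = ModelConfig()
    mesh = tet_mesh(build_shell(cfg))
    sol = solve_pressure_series(mesh, cfg.material, (2.0,))[0]
    return cfg, mesh, sol


@pytest.fixture(scope="session")
def suite_results(tmp_path_factory):
    """Full reference-suite results table (built once per test session)."""
    from septamech.experiments import paper_suite, run_suite

    out = tmp_path_factory.mktemp("suite")
    return run_suite(paper_suite(), out)


@pytest.fixture
def rng():
    return np.random.default_rng(20201919)
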