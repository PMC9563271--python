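import pytest

from deltacomm import PipelineConfig, SimConfig, normalize_log_scaled, simulate
from deltacomm.synthetic_data import default_planted_axis, write_fixture


@pytest.fixture(scope="session")
def sim_bundle():
    """Small planted fixture shared by unit tests (fast; not the acceptance
    configuration)."""
    cfg = SimConfig(
        planted_axes=[default_planted_axis()],
        n_decoy_axes=5,
        n_background_genes=80,
        cells_per_type_per_condition=60,
        seed=11,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def norm_matrix(sim_bundle):
    matrix, *_ = sim_bundle
    return normalize_log_scaled(matrix)


@pytest.fixture(scope="session")
def fixture_dir(sim_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    write_fixture(sim_bundle, out, force=True)
    return out


@pytest.fixture
def fast_config():
    return PipelineConfig(seed=11, n_perm=200)
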