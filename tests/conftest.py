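import numpy as np
import pytest

from charrdev.pipeline import RunConfig, run_pipeline
from charrdev.simulate import SimDesign, default_params, generate_design


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_design():
    return SimDesign(n_families_per_cross=3, n_offspring_per_family=12)


@pytest.fixture(scope="session")
def small_params(small_design):
    return default_params(small_design)


@pytest.fixture(scope="session")
def small_roster(small_design):
    return generate_design(small_design, seed=0)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory, small_design):
    """One full (reduced-chain) pipeline run shared by integration and
    output-schema tests."""
    out = tmp_path_factory.mktemp("pipeline")
    cfg = RunConfig(
        outdir=str(out / "run"),
        seed=11,
        design=small_design,
        iterations=900,
        burn_in=200,
        thin=2,
        n_perm=199,
        n_angle_rep=60,
        n_null_rep=40,
    )
    return run_pipeline(cfg), cfg
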