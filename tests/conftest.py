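import numpy as np
import pytest

from sirna_boundary import predict_efficacy, run_iteration
from sirna_boundary.synthetic_fixtures import FixtureConfig, generate_fixture


@pytest.fixture(scope="session")
def default_fixture():
    """The default synthetic dataset: 50 potent + 150 ineffective, seed 0."""
    ds, truth = generate_fixture(FixtureConfig(seed=0), return_truth=True)
    return ds, truth


@pytest.fixture(scope="session")
def default_run(default_fixture):
    """One full removal iteration on the default fixture, shared by tests."""
    ds, _ = default_fixture
    engine, state = run_iteration(ds)
    return ds, engine, state


@pytest.fixture(scope="session")
def default_predictions(default_run):
    ds, engine, state = default_run
    return predict_efficacy(engine, state)


@pytest.fixture(scope="session")
def small_run():
    """A smaller fixture run for tests that need a second independent run."""
    cfg = FixtureConfig(n_potent=15, n_ineffective=45, n_motif_families=3,
                        n_decoy_potent=2, seed=7)
    ds = generate_fixture(cfg)
    engine, state = run_iteration(ds)
    return ds, engine, state


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
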