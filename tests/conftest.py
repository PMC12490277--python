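import numpy as np
import pytest

import spatialfactor as sf


@pytest.fixture(scope="session")
def path3():
    """Three regions in a line: 0 - 1 - 2."""
    return sf.build_adjacency([(0, 1), (1, 2)], 3)


@pytest.fixture(scope="session")
def lattice30():
    """Desk-scale stand-in for a county map: 5 x 6 queen lattice."""
    return sf.generate_lattice(5, 6, "queen")


@pytest.fixture(scope="session")
def synth_default():
    """One synthetic dataset from the default generator settings."""
    return sf.simulate_dataset(sf.default_config(seed=11))


@pytest.fixture(scope="session")
def fitted_default(synth_default):
    """A short two-chain fit of the varying-loadings model, reused across tests."""
    model = sf.DynamicSpatialFactorModel(
        synth_default.observations, synth_default.config.graph, loadings_mode="varying"
    )
    return model.fit(n_iterations=4000, n_burnin=2000, thin=2, n_chains=2, seed=7)


@pytest.fixture(scope="session")
def fitted_constant(synth_default):
    """Short constant-loadings fit of the same dataset."""
    model = sf.DynamicSpatialFactorModel(
        synth_default.observations, synth_default.config.graph, loadings_mode="constant"
    )
    return model.fit(n_iterations=4000, n_burnin=2000, thin=2, n_chains=2, seed=9)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
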