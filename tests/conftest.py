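import numpy as np
import pytest

from cfmr import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with a strong signal, shared across fast tests."""
    cfg = SimulationConfig(
        n_individuals=800,
        n_variants=40,
        n_causal=3,
        maf=0.3,
        h2=0.4,
        beta0=0.3,
        sigma_uv=0.8,
        seed=7,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session", autouse=True)
def _warm_jit():
    """Compile the coordinate-descent kernel once before timing-sensitive
    tests run."""
    from cfmr import _lasso

    g = np.eye(3)
    b = np.array([1.0, 0.5, 0.0])
    _lasso.lasso_path_gram(g, b, np.array([0.1, 0.01]))
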