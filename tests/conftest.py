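import numpy as np
import pytest

from methylfrac import SimConfig, simulate_reference, simulate_study


@pytest.fixture(scope="session")
def small_config():
    """A fast study: 30 regions, 6 informative, light coverage."""
    return SimConfig(
        n_regions=30,
        n_informative=6,
        tissue_depth_x=8.0,
        urine_depth_x=8.0,
        n_tumor_tissue=6,
        n_normal_tissue=6,
        n_noncancer_urine=8,
        theta_grid=(0.1, 0.3),
        samples_per_theta=3,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config, seed=7)


@pytest.fixture(scope="session")
def one_region():
    """A single simulated region for read-level tests."""
    cfg = SimConfig(n_regions=1, n_informative=0, seed=11)
    regions, _ = simulate_reference(cfg)
    return regions[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
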