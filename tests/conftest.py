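import numpy as np
import pytest

from osteoscreen.simulate import SimulationConfig, simulate_screen


@pytest.fixture(scope="session")
def small_screen():
    """A modest noisy screen (160 genes, triplicates, default noise)."""
    cfg = SimulationConfig(n_kinase=120, n_phosphatase=40, seed=11)
    dataset, truth = simulate_screen(cfg)
    return dataset, truth, cfg


@pytest.fixture(scope="session")
def noiseless_screen():
    """Noise-free screen: planted effects must be recovered exactly."""
    cfg = SimulationConfig(
        n_kinase=80,
        n_phosphatase=0,
        frac_ur=0.05,
        frac_dr=0.05,
        frac_lethal=0.025,
        noise_cv=0.0,
        edge_factor=1.0,
        plate_scale_sd=0.0,
        frac_topography=0.0,
        seed=7,
    )
    dataset, truth = simulate_screen(cfg)
    return dataset, truth, cfg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
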