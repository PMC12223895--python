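import numpy as np
import pytest

from oleokin import BRIMBERG, KineticDataset, SimulationConfig, simulate_kinetics


@pytest.fixture
def brimberg_60c_dataset() -> KineticDataset:
    """Noise-free 6-point Brimberg curve with parameters typical of a 60 degC run."""
    config = SimulationConfig(
        model="brimberg",
        parameters={"k2": 0.1453, "n": 0.528},
        temperatures_c=(60.0,),
        noise_sigma=0.0,
        seed=7,
    )
    datasets, _ = simulate_kinetics(config)
    return datasets[0]


@pytest.fixture
def pfo_50c_dataset() -> KineticDataset:
    """Noise-free 6-point pseudo-first-order curve at a 50 degC-like rate."""
    config = SimulationConfig(
        model="pseudo_first_order",
        parameters={"k1": 0.01782},
        temperatures_c=(50.0,),
        noise_sigma=0.0,
        seed=11,
    )
    datasets, _ = simulate_kinetics(config)
    return datasets[0]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
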