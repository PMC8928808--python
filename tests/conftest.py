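import numpy as np
import pytest

from lamincurv import FilamentParams, GeneratorConfig, SigmoidFit


@pytest.fixture
def default_params() -> FilamentParams:
    """Filament energies with the geometric bending constant 0.19 k_BT um^2."""
    return FilamentParams(binding_energy_E=4.0, contact_coeff_a=8.0)


@pytest.fixture
def noiseless_config() -> GeneratorConfig:
    return GeneratorConfig(seed=7, noise_sd=0.0)


@pytest.fixture
def percent_sigmoid() -> SigmoidFit:
    """Rupture-frequency response in percent: midpoint at 0.5 1/um."""
    return SigmoidFit(amplitude_B=34.0, epsilon=4.0, alpha=8.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
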