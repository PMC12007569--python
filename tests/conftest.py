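import numpy as np
import pytest

from gatescape import default_gates
from gatescape.synthetic import SyntheticEnsembleParams, build_template, generate_ensemble


@pytest.fixture(scope="session")
def template():
    return build_template()


@pytest.fixture(scope="session")
def gates():
    return default_gates()


@pytest.fixture(scope="session")
def ladder_ensemble():
    """Noise-free 11-model ladder spanning t in [0, 1]."""
    params = SyntheticEnsembleParams(
        n_models=11, noise_sigma=0.0, seed=1,
        t_values=tuple(np.linspace(0.0, 1.0, 11)))
    return generate_ensemble(params)


@pytest.fixture(scope="session")
def noisy_ensemble():
    """Small noisy ensemble with the default study conditions."""
    params = SyntheticEnsembleParams(n_models=60, noise_sigma=0.2, seed=42)
    return generate_ensemble(params)
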