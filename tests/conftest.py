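import numpy as np
import pytest

from phenolflux.diffusion import DiffusionParams, ParticleSpec, SuspensionSpec


@pytest.fixture(scope="session")
def particle():
    return ParticleSpec()


@pytest.fixture(scope="session")
def suspension():
    return SuspensionSpec()


@pytest.fixture(scope="session")
def default_params(particle):
    # rate 0.01/min: half-extraction ~2.6 min, typical of the fast conditions
    return DiffusionParams.from_rate(0.01, particle, Cs0=0.0079)


@pytest.fixture(scope="session")
def times_30min():
    return np.array([0.0, 2.5, 5.0, 7.5, 10.0, 15.0, 20.0, 25.0, 30.0])
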