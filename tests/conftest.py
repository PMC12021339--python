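import numpy as np
import pytest

from mpragelike import (
    ContrastVolume,
    default_acquisition,
)
from mpragelike.phantom import (
    FieldSpec,
    NoiseSpec,
    PhantomSpec,
    load_default_tissues,
    simulate_phantom,
)


@pytest.fixture(scope="session")
def acq():
    return default_acquisition()


@pytest.fixture(scope="session")
def tissues():
    return load_default_tissues()


@pytest.fixture(scope="session")
def noiseless_spec():
    return PhantomSpec(shape=(32, 32, 32), seed=7, noise=NoiseSpec("none", 0.0))


@pytest.fixture(scope="session")
def noiseless_sim(noiseless_spec):
    """Small noiseless small-angle phantom shared across tests."""
    return simulate_phantom(noiseless_spec)


@pytest.fixture(scope="session")
def uniform_field_sim(noiseless_spec):
    """Same geometry/seed as noiseless_sim but with unit transmit/receive."""
    from dataclasses import replace

    spec = replace(
        noiseless_spec,
        transmit_field=FieldSpec(1.0, 1.0),
        receive_field=FieldSpec(1.0, 1.0),
    )
    return simulate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_volume(data, spacing=(1.0, 1.0, 1.0), weighting="T1w"):
    return ContrastVolume(np.asarray(data, float), spacing=spacing, weighting=weighting)
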