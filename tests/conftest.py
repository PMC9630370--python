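import numpy as np
import pytest

from oarseg.phantom import Ellipsoid, PhantomSpec, default_spec, generate_phantom


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Deterministic 64^3 phantom with exact two-value anatomy (body 40, organ 200)."""
    return generate_phantom(default_spec(noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_phantom():
    return generate_phantom(default_spec(noise_sd=15.0, seed=7))


@pytest.fixture()
def small_spec():
    """A 32^3 phantom spec that renders quickly."""
    return PhantomSpec(
        shape=(32, 32, 32),
        spacing=(1.0, 1.0, 1.0),
        body=Ellipsoid((16.0, 16.0, 16.0), (13.0, 13.0, 13.0), 40.0),
        organs=((1, Ellipsoid((18.0, 15.0, 16.0), (5.0, 6.0, 4.5), 200.0)),),
        noise_sd=10.0,
        seed=3,
    )
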