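import numpy as np
import pytest

from madseg.environment import EnvConfig
from madseg.phantoms import PhantomSpec, make_phantom
from madseg.policy import NetworkSpec, PolicyNetwork, ValueNetwork


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, gap-free circular phantom."""
    return make_phantom(PhantomSpec(image_size=128, seed=3))


@pytest.fixture(scope="session")
def gappy_phantom():
    """Phantom with 30% total gaps, largest 20%."""
    return make_phantom(PhantomSpec(image_size=192, gap_total_frac=0.3,
                                    gap_max_frac=0.2, seed=5))


@pytest.fixture(scope="session")
def easy_phantom():
    """Mildly noisy, lightly gapped phantom used for pipeline tests."""
    return make_phantom(PhantomSpec(image_size=128, gap_total_frac=0.15,
                                    gap_max_frac=0.03, noise_sigma=0.25,
                                    seed=9))


@pytest.fixture(scope="session")
def small_spec():
    return NetworkSpec(receptive_field=8)


@pytest.fixture(scope="session")
def small_policy(small_spec):
    return PolicyNetwork(small_spec, seed=0)


@pytest.fixture(scope="session")
def small_value(small_spec):
    return ValueNetwork(small_spec, seed=1)


@pytest.fixture(scope="session")
def small_env_config():
    return EnvConfig(receptive_field=8)
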