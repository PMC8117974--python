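import numpy as np
import pytest

from nuva import PhoneInventory, Posteriorgram, SynthConfig, synth_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def inventory():
    return PhoneInventory.default()


def random_posteriorgram(rng, n_frames, inventory=None, alpha=1.0):
    inventory = inventory or PhoneInventory.default()
    probs = rng.dirichlet(np.full(len(inventory), alpha), size=n_frames)
    return Posteriorgram(probs, inventory)


@pytest.fixture(scope="session")
def small_study():
    """A 30-word, 3-patient replica shared across slow-ish tests."""
    return synth_study(SynthConfig(n_words=30, n_patients=3, seed=7))
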