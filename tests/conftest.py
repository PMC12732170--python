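import numpy as np
import pytest

from thymixer import generate_cohort
from thymixer.mixer import MixerBlock, MixerNet, ModelConfig


@pytest.fixture(scope="session")
def tiny_cohort():
    """2 healthy + 1 benign + 1 malignant, short stacks — fast fixture."""
    return generate_cohort(n_healthy=2, n_benign=1, n_malignant=1,
                           slices_per_scan=(9, 12), seed=7)


@pytest.fixture(scope="session")
def small_net():
    """A seeded reduced-backbone classifier (untrained)."""
    return MixerNet(ModelConfig(backbone="small", channels=64), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_block(s, c, seed=0, h_s=None, h_c=None):
    return MixerBlock(tokens=s, channels=c, h_s=h_s or s, h_c=h_c or c,
                      rng=np.random.default_rng(seed))
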