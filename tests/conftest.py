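import numpy as np
import pytest

from facecontrast.stimuli import build_stimulus_set
from facecontrast.template import default_template


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture(scope="session")
def stimulus_set(template):
    """One shared 5/5/10/15 stimulus complement (seeded, immutable)."""
    return build_stimulus_set(template, seed=7)


@pytest.fixture(scope="session")
def feature_strength(stimulus_set):
    return stimulus_set.feature_strength_matrix()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
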