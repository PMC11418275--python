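import numpy as np
import pytest

from mlgyolo import SceneSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_spec():
    """Small scene used by training tests: few large fruit, mild clutter."""
    return SceneSpec(width=64, height=64, fruit_count=(2, 4), fruit_radius=(7, 12),
                     leaf_count=(1, 3), illumination=(1.0, 1.0), seed=0)
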