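import numpy as np
import pytest

import sgsnet as sg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_model():
    """One shared tiny detector (fresh weights, eval mode by default)."""
    model = sg.SGSNet(sg.builtin_config("tiny"), seed=7)
    model.set_training(False)
    return model


@pytest.fixture(scope="session")
def small_scenes():
    """A handful of 320-px scenes with a few objects each."""
    return [sg.render_scene(500 + i, n_objects=3, size=320) for i in range(4)]
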