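import numpy as np
import pytest

from midline_game import Handedness, default_config, run_session
from midline_game.players import make_profile


@pytest.fixture
def stage1():
    return default_config(1)


@pytest.fixture
def unimpaired():
    return make_profile("unimpaired")


@pytest.fixture
def impaired_severe():
    return make_profile("impaired", 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def quick_session(stage1, unimpaired):
    """A short deterministic session for serialization/dashboard tests."""
    cfg = default_config(1, duration_s=40.0)
    return run_session(cfg, Handedness.right, unimpaired, 11, child_id="child-x")
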