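import numpy as np
import pytest

from cognav import AgentConfig, load_fixture
from cognav.generative_model import CognitiveModel


@pytest.fixture(scope="session")
def fixtures():
    """All packaged layouts, loaded once."""
    from cognav.room_world import FIXTURES

    return {name: load_fixture(name) for name in FIXTURES}


@pytest.fixture()
def tiny_model():
    """A 3-state model: two learned states sharing nothing, one imagined.

    State 0 emits "red", state 1 emits "blue" (both well learned); state 2
    is imagined: uniform observation column, bound to pose (2, 0).
    """
    m = CognitiveModel.initial(origin=(0, 0))
    m.grow_color("red")
    m.grow_color("blue")
    m.A_o[0, 0] += 5.0
    m.grow_pose((1, 0))
    s1 = m.grow_state()
    m.bind_pose_to_state((1, 0), s1)
    m.A_o[1, s1] += 5.0
    m.grow_pose((2, 0))
    s2 = m.grow_state()
    m.bind_pose_to_state((2, 0), s2)
    return m


@pytest.fixture()
def config():
    return AgentConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
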