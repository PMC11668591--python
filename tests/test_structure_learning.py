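"""Map expansion over predictions, Dirichlet learning, negative learning."""

import numpy as np
import pytest

from cognav.actions import Action, MOVES, opposite
from cognav.agent import Agent, AgentConfig
from cognav.generative_model import CognitiveModel, normalize
from cognav.inference import BeliefState, MODE_LOST, initial_belief
from cognav.room_world import StepResult, WorldPose, load_fixture, step as world_step
from cognav.structure_learning import (
    imagine_frontier,
    learn_from_transition,
    map_confidence,
    negative_update,
)

OPEN_EAST_ONLY = (True, False, True, True)  # walls N, S, W


def _fresh(eps=0.025, **kw):
    m = CognitiveModel.initial(origin=(0, 0), eps=eps, **kw)
    m.grow_color("red")
    m.A_o[0, 0] += 1.0
    return m


def test_open_door_spawns_imagined_state_with_uniform_observations():
    m = _fresh()
    m.grow_color("blue")
    belief = initial_belief(m)
    obs = StepResult(observation="red", collisions=OPEN_EAST_ONLY, moved=False)
    events = imagine_frontier(belief, m, obs)
    assert m.n_states == 2 and m.n_poses == 2
    s2 = m.state_of_pose((1, 0))
    assert s2 is not None
    np.testing.assert_allclose(normalize(m.A_o[:, s2]), [0.5, 0.5])  # no color committed
    assert m.pose_successor((0, 0), Action.EAST) == (1, 0)
    assert any(e.kind == "state" for e in events)


def test_wall_adds_self_transition_without_growth():
    m = _fresh()
    belief = initial_belief(m)
    obs = StepResult(observation="red", collisions=(True, True, True, True), moved=False)
    before = m.B_s.copy()
    imagine_frontier(belief, m, obs)
    assert m.n_states == 1 and m.n_poses == 1
    for a in MOVES:
        assert m.B_s[0, 0, int(a)] == pytest.approx(before[0, 0, int(a)] + m.eta_im)


def test_reimagining_is_idempotent():
    m = _fresh()
    belief = initial_belief(m)
    obs = StepResult(observation="red", collisions=OPEN_EAST_ONLY, moved=False)
    imagine_frontier(belief, m, obs)
    snap = m.B_s.copy()
    dims = m.dims()
    imagine_frontier(belief, m, obs)
    np.testing.assert_array_equal(m.B_s, snap)
    assert m.dims() == dims


def test_expansion_paused_while_lost():
    m = _fresh()
    lost = BeliefState(q_s=np.array([1.0]), pose=(0, 0), mode=MODE_LOST)
    obs = StepResult(observation="red", collisions=OPEN_EAST_ONLY, moved=False)
    with pytest.raises(ValueError):
        imagine_frontier(lost, m, obs)


def test_experienced_link_beats_imagined_link():
    """One real crossing must outweigh a same-age imagined link.

    Closed form with eta_exp=1, eta_im=0.2, eps=0.1: the experienced
    count is eps + eta_im + eta_exp = 1.3 vs the imagined eps + eta_im
    = 0.3, so the normalized probability is strictly higher.
    """
    m = _fresh(eps=0.1, eta_im=0.2, eta_exp=1.0)
    m.grow_color("blue")
    belief = initial_belief(m)
    obs = StepResult(observation="red", collisions=(True, False, False, True), moved=False)
    imagine_frontier(belief, m, obs)  # imagines East and South neighbors
    s_e = m.state_of_pose((1, 0))
    s_s = m.state_of_pose((0, -1))
    p_before = m.transition(Action.EAST)[s_e, 0]
    learn_from_transition(m, 0, Action.EAST, s_e, "blue")
    t_e = m.transition(Action.EAST)[s_e, 0]
    t_s = m.transition(Action.SOUTH)[s_s, 0]
    assert t_e > p_before  # experience strictly increases the belief
    assert t_e > t_s  # and beats the merely imagined link
    assert m.B_s[s_e, 0, int(Action.EAST)] == pytest.approx(0.1 + 0.2 + 1.0)
    # bi-directional: the reverse transition was credited too
    assert m.transition(Action.WEST)[0, s_e] > 0.5


def test_repeated_experience_is_monotone():
    m = _fresh()
    m.grow_color("blue")
    belief = initial_belief(m)
    obs = StepResult(observation="red", collisions=OPEN_EAST_ONLY, moved=False)
    imagine_frontier(belief, m, obs)
    s2 = m.state_of_pose((1, 0))
    probs = []
    for _ in range(5):
        learn_from_transition(m, 0, Action.EAST, s2, "blue")
        probs.append(m.transition(Action.EAST)[s2, 0])
    assert all(b > a for a, b in zip(probs, probs[1:]))


def test_negative_update_flips_argmax_to_self_and_floors_at_eps():
    m = _fresh()
    m.grow_color("blue")
    belief = initial_belief(m)
    obs = StepResult(observation="red", collisions=OPEN_EAST_ONLY, moved=False)
    imagine_frontier(belief, m, obs)
    s2 = m.state_of_pose((1, 0))
    learn_from_transition(m, 0, Action.EAST, s2, "blue")
    assert np.argmax(m.transition(Action.EAST)[:, 0]) == s2
    for _ in range(3):
        negative_update(m, belief, Action.EAST)
    t = m.transition(Action.EAST)[:, 0]
    assert np.argmax(t) == 0  # successor flipped to self
    assert m.B_s[s2, 0, int(Action.EAST)] >= m.eps  # floored, never below eps
    assert m.pose_successor((0, 0), Action.EAST) is None  # edge suppressed


def test_reexperience_restores_positive_belief():
    """Negative learning is plastic: walking through the door again
    restores the positive transition belief (no absorbing state)."""
    m = _fresh()
    m.grow_color("blue")
    belief = initial_belief(m)
    obs = StepResult(observation="red", collisions=OPEN_EAST_ONLY, moved=False)
    imagine_frontier(belief, m, obs)
    s2 = m.state_of_pose((1, 0))
    learn_from_transition(m, 0, Action.EAST, s2, "blue")
    negative_update(m, belief, Action.EAST)
    assert np.argmax(m.transition(Action.EAST)[:, 0]) == 0
    # the obstacle is gone: the open side is re-imagined, then re-crossed
    imagine_frontier(belief, m, obs)
    assert m.pose_successor((0, 0), Action.EAST) == (1, 0)
    learn_from_transition(m, 0, Action.EAST, s2, "blue")
    learn_from_transition(m, 0, Action.EAST, s2, "blue")
    assert np.argmax(m.transition(Action.EAST)[:, 0]) == s2


def test_map_confidence_trivial_cases():
    lay = load_fixture("3x3")
    start = WorldPose(0, 0)
    # an all-epsilon model with no states fails with coverage deficit
    empty = CognitiveModel.initial()
    empty.grow_color("red")
    val, passed, missing = map_confidence(empty, lay, start)
    assert not passed and missing > 0
    # a model whose counts exactly mirror the truth passes with conf -> 1
    m = CognitiveModel.initial()
    m.grow_color("x")
    pose_of = {}
    for i, (x, y) in enumerate(lay.rooms()):
        p = (x - start.x, y - start.y)
        if m.state_of_pose(p) is None:
            m.grow_pose(p) if p not in m.poses else None
            s = m.grow_state() if i else 0
            if i:
                m.bind_pose_to_state(p, s)
        pose_of[(x, y)] = m.state_of_pose(p)
    from cognav.actions import DELTA

    for (x, y) in lay.rooms():
        for a in MOVES:
            if lay.has_door(WorldPose(x, y), a):
                d = DELTA[a]
                m.B_s[pose_of[(x + d[0], y + d[1])], pose_of[(x, y)], int(a)] += 50.0
    val, passed, missing = map_confidence(m, lay, start)
    assert passed and val > 0.95 and missing == 0


def test_expansion_before_experience_invariant():
    """After every confidently visited room, the model already contains a
    successor state behind each of its open doors."""
    lay = load_fixture("4x4")
    agent = Agent(AgentConfig(), seed=11)
    pose = WorldPose(0, 0)
    _, obs = world_step(lay, pose, Action.STAY)
    for _ in range(30):
        agent.perceive(obs)
        if agent.belief.mode == "normal":
            internal = agent.belief.pose
            for i, a in enumerate(MOVES):
                if not obs.collisions[i]:
                    from cognav.actions import DELTA

                    d = DELTA[a]
                    nxt = (internal[0] + d[0], internal[1] + d[1])
                    assert agent.model.state_of_pose(nxt) is not None
        act = agent.plan()
        pose, obs = world_step(lay, pose, act)
        agent.last_action = Action(act)


def test_exploration_terminates_exactly_at_first_pass(fixtures):
    from cognav import run_episode
    from cognav.structure_learning import map_confidence as mc

    lay = fixtures["3x3"]
    res = run_episode(lay, WorldPose(0, 0), "explore", seed=3, max_steps=200)
    assert res.outcome == "learned"
    _, passed, _ = mc(res.agent.model, lay, WorldPose(0, 0))
    assert passed
    assert res.steps >= 11  # never beats the coverage oracle
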