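"""State/pose inference: Bayes updates, free energy, confidence gating."""

import numpy as np
import pytest

from cognav.actions import Action
from cognav.agent import Agent, AgentConfig
from cognav.generative_model import CognitiveModel
from cognav.inference import (
    BeliefState,
    MODE_LOST,
    MODE_NORMAL,
    check_confidence,
    compute_vfe,
    initial_belief,
    update_belief,
)
from cognav.room_world import StepResult, WorldPose, load_fixture, step as world_step

NO_WALLS = (False, False, False, False)


def _two_state_toy():
    """Two states, A_o = [[.9, .1], [.1, .9]], uniform prior and transitions."""
    m = CognitiveModel.initial(origin=(0, 0), eps=1.0)
    m.grow_color("red")
    m.grow_color("blue")
    m.grow_pose((1, 0))
    s1 = m.grow_state()
    # shape counts so columns normalize to [.9,.1] / [.1,.9]
    m.A_o[:, 0] = [9.0, 1.0]
    m.A_o[:, s1] = [1.0, 9.0]
    m.B_s[...] = 1.0  # uniform transitions for every action
    m.A_p[...] = 1.0  # uninformative position factor
    return m


def test_two_state_hand_bayes():
    """Uniform prior x likelihood [.9,.1] must give the posterior [.9,.1].

    Expected value computed by enumerating the joint by hand:
    q(s) = P(o|s) * 0.5 / sum_s P(o|s) * 0.5 = [.9, .1].
    """
    m = _two_state_toy()
    belief = BeliefState(q_s=np.array([0.5, 0.5]), pose=(0, 0))
    obs = StepResult(observation="red", collisions=NO_WALLS, moved=True)
    out = update_belief(belief, m, Action.EAST, obs)
    np.testing.assert_allclose(out.q_s, [0.9, 0.1], atol=1e-12)


def test_vfe_equals_neg_log_evidence_at_exact_posterior():
    """Hand enumeration: evidence = 0.5*0.9 + 0.5*0.1 = 0.5, F = -log 0.5.

    Evaluated with the position factor suspended (lost mode) so the only
    factors are the enumerable prior and observation likelihood.  Any
    perturbed normalized belief must have strictly larger F (the KL gap
    to the exact posterior is positive).
    """
    m = _two_state_toy()
    prev = BeliefState(q_s=np.array([0.5, 0.5]), pose=(0, 0), mode=MODE_LOST)
    obs = StepResult(observation="red", collisions=NO_WALLS, moved=True)
    post = update_belief(prev, m, Action.EAST, obs)
    np.testing.assert_allclose(post.q_s, [0.9, 0.1], atol=1e-12)
    f_exact = compute_vfe(prev, post, m, Action.EAST, obs)
    np.testing.assert_allclose(f_exact, -np.log(0.5), atol=1e-10)
    for q in ([0.5, 0.5], [0.8, 0.2], [0.99, 0.01]):
        other = BeliefState(q_s=np.array(q), pose=post.pose, mode=post.mode)
        assert compute_vfe(prev, other, m, Action.EAST, obs) > f_exact + 1e-12


def test_one_observation_localizes_in_distinct_color_maze():
    """With all colors distinct and a learned map, a single observation
    pins the posterior to one state."""
    lay = load_fixture("3x3")
    from cognav import run_episode

    res = run_episode(lay, WorldPose(0, 0), "explore", seed=0, max_steps=200)
    agent = res.agent
    # drop the agent anywhere, uniform belief, observation only
    m = agent.model
    target = WorldPose(2, 2)
    _, obs = world_step(lay, target, Action.STAY)
    lost = BeliefState(
        q_s=np.full(m.n_states, 1 / m.n_states), pose=(0, 0), mode=MODE_LOST
    )
    out = update_belief(lost, m, Action.STAY, obs)
    assert out.confidence > 0.8  # near-one-hot up to epsilon smoothing
    assert m.pose_of_state(out.map_state) == (2, 2)
    # and the position factor then makes it exact on the next normal step
    assert out.q_s[out.map_state] > 10 * np.sort(out.q_s)[-2]


def test_aliased_t_maze_splits_three_ways():
    """The aliased stem-bottom color is shared by three rooms; from a
    uniform lost belief the posterior splits over those three states."""
    lay = load_fixture("T_maze_alias")
    from cognav import run_episode

    res = run_episode(lay, WorldPose(2, 0), "explore", seed=0, max_steps=200)
    m = res.agent.model
    _, obs = world_step(lay, WorldPose(2, 0), Action.STAY)
    lost = BeliefState(q_s=np.full(m.n_states, 1 / m.n_states), pose=(0, 0), mode=MODE_LOST)
    out = update_belief(lost, m, Action.STAY, obs)
    top = np.sort(out.q_s)[::-1]
    assert top[2] > 0.2 and top[:3].sum() > 0.9  # three-way split
    assert out.confidence < 0.5


def test_confidence_hysteresis_and_pose_reanchor(tiny_model):
    m = tiny_model
    confident = BeliefState(q_s=np.array([0.9, 0.05, 0.05]), pose=(5, 5))
    assert check_confidence(confident, m, 0.5, 0.7).mode == MODE_NORMAL
    shaky = BeliefState(q_s=np.array([0.4, 0.35, 0.25]), pose=(5, 5))
    assert check_confidence(shaky, m, 0.5, 0.7).mode == MODE_LOST
    # while lost, middling confidence does not recover (hysteresis) ...
    lost = BeliefState(q_s=np.array([0.6, 0.3, 0.1]), pose=(5, 5), mode=MODE_LOST)
    assert check_confidence(lost, m, 0.5, 0.7).mode == MODE_LOST
    # ... but high confidence does, re-anchoring the pose to the MAP state
    sure = BeliefState(q_s=np.array([0.05, 0.9, 0.05]), pose=(5, 5), mode=MODE_LOST)
    rec = check_confidence(sure, m, 0.5, 0.7)
    assert rec.mode == MODE_NORMAL and rec.pose == (1, 0)


def test_kidnap_freezes_learning_while_lost():
    """A silent relocation must not corrupt the learned count tensors."""
    lay = load_fixture("Donuts")
    from cognav import run_episode

    res = run_episode(lay, WorldPose(0, 0), "explore", seed=4, max_steps=300)
    agent = res.agent
    tensors = (agent.model.A_o.copy(), agent.model.A_p.copy(), agent.model.B_s.copy())
    n_states = agent.model.n_states
    # kidnap to the far corner; first contradictory observation
    pose = WorldPose(4, 3)
    _, obs = world_step(lay, pose, Action.STAY)
    agent.last_action = Action.STAY
    agent.perceive(obs)
    assert agent.model.n_states == n_states
    for before, after in zip(tensors, (agent.model.A_o, agent.model.A_p, agent.model.B_s)):
        np.testing.assert_array_equal(before, after)


def test_lost_agent_relocalizes_walking_aliased_t_maze():
    """The kidnapped-at-the-stem scenario: divided confidence over the
    three same-colored rooms resolves to full confidence within four
    observations while walking up the stem."""
    lay = load_fixture("T_maze_alias")
    from cognav import run_episode

    res = run_episode(lay, WorldPose(0, 3), "explore", seed=1, max_steps=200)
    agent = res.agent
    agent.last_action = Action.STAY
    # the agent keeps its map but has no idea where it is
    agent.belief = BeliefState(
        q_s=np.full(agent.model.n_states, 1 / agent.model.n_states),
        pose=(0, 0),
        mode=MODE_LOST,
    )
    pose = WorldPose(2, 0)  # silently dropped at the stem bottom
    _, obs = world_step(lay, pose, Action.STAY)
    agent.perceive(obs)
    confidences = [agent.belief.confidence]
    for action in [Action.NORTH, Action.NORTH, Action.NORTH, Action.NORTH]:
        if agent.belief.confidence > 0.99:
            break
        pose, obs = world_step(lay, pose, action)
        agent.last_action = action
        agent.perceive(obs)
        confidences.append(agent.belief.confidence)
    assert confidences[0] < 0.5  # initial ambiguity
    assert agent.belief.confidence > 0.99  # resolved within four steps
    internal = agent.belief.pose
    assert agent.model.state_of_pose(internal) == agent.belief.map_state


def test_zero_likelihood_falls_back_to_uniform_lost():
    m = _two_state_toy()
    m.A_o[0, :] = 0.0  # degenerate: the observed color impossible everywhere
    belief = BeliefState(q_s=np.array([1.0, 0.0]), pose=(0, 0))
    obs = StepResult(observation="red", collisions=NO_WALLS, moved=True)
    out = update_belief(belief, m, Action.EAST, obs)
    assert out.mode == MODE_LOST
    np.testing.assert_allclose(out.q_s, [0.5, 0.5])
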