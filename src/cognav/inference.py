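"""State and pose inference with confidence gating and re-localization.

Per-step filtering posterior over model states: the belief is updated by
combining the transition prior (previous posterior pushed through the
state transition model for the executed action), the observation
likelihood of the perceived floor color, and — in normal mode — the
position likelihood of the internally tracked pose.

When the posterior's confidence (its maximum) drops below a certainty
threshold, e.g. after a silent kidnapping, the agent enters *lost* mode:
it suspends reliance on its position information, freezes the pose
estimate and all parameter learning, and re-localizes on observations
alone until confidence recovers, at which point the pose is re-anchored
to the most probable state's bound pose.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .actions import Action, DELTA
from .generative_model import CognitiveModel, Pose
from .room_world import StepResult

MODE_NORMAL = "normal"
MODE_LOST = "lost"


@dataclass(frozen=True)
class BeliefState:
    """Categorical posterior over states plus a pose point estimate."""

    q_s: np.ndarray
    pose: Pose
    mode: str = MODE_NORMAL

    @property
    def confidence(self) -> float:
        return float(self.q_s.max())

    @property
    def entropy(self) -> float:
        q = self.q_s[self.q_s > 0]
        return float(-(q * np.log(q)).sum())

    @property
    def map_state(self) -> int:
        return int(np.argmax(self.q_s))

    def padded_to(self, n_states: int) -> "BeliefState":
        """Extend q_s with zero mass for states grown since the update."""
        extra = n_states - self.q_s.size
        if extra <= 0:
            return self
        return replace(self, q_s=np.pad(self.q_s, (0, extra)))


def initial_belief(model: CognitiveModel, origin: Pose = (0, 0)) -> BeliefState:
    q = np.zeros(model.n_states)
    q[model.state_of_pose(origin)] = 1.0
    return BeliefState(q_s=q, pose=tuple(origin))


def _factors(
    belief: BeliefState, model: CognitiveModel, action: Action, obs: StepResult, pose: Pose
) -> tuple[np.ndarray, np.ndarray]:
    """(likelihood factor, transition prior) for the current step."""
    q_prev = belief.padded_to(model.n_states).q_s
    if obs.moved:
        prior = model.transition(action) @ q_prev
    else:
        # Proprioception says the pose did not change (wall bump or
        # Stay): the state prior carries over unchanged.
        prior = q_prev
    lik = model.obs_likelihood()[model.color_index(obs.observation), :].copy()
    lik = lik * _move_consistency(model, action, obs)
    if belief.mode == MODE_NORMAL:
        lik = lik * model.state_given_pose(pose)
    return lik, prior


#: Likelihood of the proprioceptive move/bump outcome under a state that
#: disagrees with it (a believed-open side that did not let the agent
#: through, or a believed wall it walked through).
SLIP = 0.1


def _move_consistency(model: CognitiveModel, action: Action, obs: StepResult) -> np.ndarray:
    """Per-state likelihood of whether the last move succeeded.

    Proprioception reports if the agent changed rooms.  A state whose
    bound pose has a believed-open side in the attempted direction is
    inconsistent with a bump, and one with a remembered wall is
    inconsistent with a successful move; sides the model knows nothing
    about stay neutral.  Without this factor a lost agent that bumps a
    wall gains no evidence and can re-plan the same failed move forever.
    """
    action = Action(action)
    factor = np.ones(model.n_states)
    if action == Action.STAY:
        return factor
    for pose, s in model._pose_state.items():
        key = (pose, action)
        if key in model.blocked:
            believed = "wall"
        elif model.B_p.get(key) is not None:
            believed = "open"
        else:
            continue
        if obs.moved and believed == "wall":
            factor[s] = SLIP
        elif not obs.moved and believed == "open":
            factor[s] = SLIP
    return factor


def update_belief(
    belief: BeliefState,
    model: CognitiveModel,
    action: Action,
    obs: StepResult,
    certainty_threshold: float = 0.5,
    novel_color: bool = False,
    surprise_slack: float = 1.0,
) -> BeliefState:
    """One filtering step; the observed color must already be in support.

    The pose estimate advances by the pose increment of ``action`` when
    the world reports a room transition (proprioception); it is frozen in
    lost mode.

    A silent relocation cannot be read off the *normalized* posterior —
    the position factor keeps it confidently wrong — so the trigger is
    surprise of the observation under the dead-reckoned state: the state
    bound to the advanced pose estimate.  An un-visited state has a
    uniform observation column and its surprise is exactly
    ``log n_colors``, so the threshold ``log n_colors + surprise_slack``
    is never tripped by honest frontier visits; a learned state whose
    color no longer matches exceeds it at once.  When tripped, the agent
    drops the position factor, re-infers from the observation alone and
    goes lost.  A step whose color was only just added to the support is
    exempt: a novel color is maximally surprising yet contradicts
    nothing.  A zero-likelihood observation falls back to a uniform
    posterior and lost mode.
    """
    mode = belief.mode
    pose = tuple(belief.pose)
    if obs.moved and mode == MODE_NORMAL:
        d = DELTA[Action(action)]
        pose = (pose[0] + d[0], pose[1] + d[1])
    lik, prior = _factors(belief, model, action, obs, pose)
    joint = lik * prior
    total = joint.sum()
    if not np.isfinite(total) or total <= 1e-300:
        q = np.full(model.n_states, 1.0 / model.n_states)
        return BeliefState(q_s=q, pose=belief.pose, mode=MODE_LOST)
    surprised = False
    if mode == MODE_NORMAL and not novel_color:
        tracked = model.state_of_pose(pose)
        if tracked is not None:
            p_obs = model.obs_likelihood()[model.color_index(obs.observation), tracked]
            surprised = -np.log(max(p_obs, 1e-300)) > np.log(max(model.n_colors, 2)) + surprise_slack
    q = joint / total
    if mode == MODE_NORMAL and (surprised or float(q.max()) < certainty_threshold):
        # Contradictory evidence: this step's re-estimation relies on the
        # observation alone — the carried-over prior is exactly what is
        # suspected of being wrong.  States are weighted by how much they
        # have actually been observed (the A_o column mass): without this
        # empirical prior the many never-observed states, each compatible
        # with anything, soak up most of the posterior and localization
        # in a young map can never recover.  Later lost-mode steps
        # re-combine the observation with the propagated prior.
        lik_obs = model.obs_likelihood()[model.color_index(obs.observation), :]
        weight = model.A_o.sum(axis=0)
        q = lik_obs * weight
        q = q / q.sum()
        return BeliefState(q_s=q, pose=belief.pose, mode=MODE_LOST)
    return BeliefState(q_s=q, pose=pose, mode=mode)


def check_confidence(
    belief: BeliefState,
    model: CognitiveModel,
    threshold: float = 0.5,
    recovery_threshold: float = 0.7,
) -> BeliefState:
    """Apply the confidence hysteresis and re-anchor the pose on recovery.

    Below ``threshold`` the agent switches to lost mode (learning and
    expansion pause); while lost, reaching ``recovery_threshold`` returns
    it to normal mode with the pose re-anchored to the bound pose of the
    most probable state.  The gap between the two thresholds prevents
    mode flapping.
    """
    if belief.mode == MODE_NORMAL and belief.confidence < threshold:
        return replace(belief, mode=MODE_LOST)
    if belief.mode == MODE_LOST and belief.confidence >= recovery_threshold:
        anchor = model.pose_of_state(belief.map_state)
        if anchor is None:  # pragma: no cover - every state is bound
            anchor = belief.pose
        return replace(belief, mode=MODE_NORMAL, pose=tuple(anchor))
    return belief


def compute_vfe(
    prev_belief: BeliefState,
    belief: BeliefState,
    model: CognitiveModel,
    action: Action,
    obs: StepResult,
) -> float:
    """Variational free energy of the current step's factors.

    ``F = E_q[log q - log(lik * prior)]`` where the likelihood and prior
    come from ``prev_belief`` and the executed action, and the
    expectation is under the (candidate) posterior ``belief``.  With the
    exact filtering posterior this equals the negative log evidence of
    the step, and it is strictly larger for any other normalized belief.
    """
    lik, prior = _factors(prev_belief, model, action, obs, tuple(belief.pose))
    q = belief.padded_to(model.n_states).q_s
    mask = q > 0
    log_joint = np.log(np.maximum(lik * prior, 1e-300))
    return float((q[mask] * (np.log(q[mask]) - log_joint[mask])).sum())
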