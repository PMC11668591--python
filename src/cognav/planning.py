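"""Policy construction and expected-free-energy (EFE) scoring.

Candidate policies are built one per reachable target state: the
shortest action sequence to that state's pose under the believed
(deterministic) position-transition map, plus the Stay policy — no
exhaustive branching over action sequences, which keeps 13-14-step
horizons cheap.

Each policy is scored by rolling the state belief forward through the
transition model (padding with Stay to the horizon so totals are
comparable across path lengths) and summing, per predicted step:

* state information gain — the mutual information between the predicted
  state and the predicted observation (expected KL from prior to
  posterior belief), which is non-negative by construction;
* parameter information gain — the expected Dirichlet-count KL of the
  observation-likelihood and transition updates the step would trigger,
  a novelty bonus that draws the agent toward states and transitions
  with near-empty counts (imagined, un-visited ones above all);
* utility — the expected log preference of the predicted observation;
* collision risk — probability mass assigned to stepping into a side
  the agent has evidence is blocked.

Action selection samples from a softmax over negative EFE tempered by
``gamma``; only the first action is executed and the agent re-plans
every step.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln

from .actions import Action, MOVES, N_ACTIONS
from .generative_model import CognitiveModel, Pose, Preference
from .inference import BeliefState

MAX_HORIZON = 14


@dataclass(frozen=True)
class Policy:
    """A candidate action sequence aimed at ``target`` (a state id)."""

    actions: tuple[Action, ...]
    target: int | None = None

    def __post_init__(self):
        if not (1 <= len(self.actions)):
            raise ValueError("a policy holds at least one action")


@dataclass
class EFERecord:
    """Per-step EFE decomposition of one policy; total is the step sum."""

    info_gain_state: list[float] = field(default_factory=list)
    info_gain_params: list[float] = field(default_factory=list)
    utility: list[float] = field(default_factory=list)
    collision_risk: list[float] = field(default_factory=list)

    @property
    def total(self) -> float:
        per_step = [
            -igs - igp - u + c
            for igs, igp, u, c in zip(
                self.info_gain_state, self.info_gain_params, self.utility, self.collision_risk
            )
        ]
        return float(sum(per_step))


def enumerate_policies(
    belief: BeliefState, model: CognitiveModel, horizon: int
) -> list[Policy]:
    """One shortest-path policy per state reachable within the horizon.

    Paths follow the believed position map (collision-suppressed edges
    excluded) from the pose of the currently most probable state.  The
    Stay policy is always included.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    horizon = min(horizon, MAX_HORIZON)
    root = model.pose_of_state(belief.map_state)
    if root is None:  # pragma: no cover - every state is bound to a pose
        root = tuple(belief.pose)
    policies = [Policy(actions=(Action.STAY,), target=belief.map_state)]
    emitted: set[tuple[Action, ...]] = set()
    seen = {root}
    frontier = deque([(root, ())])
    while frontier:
        pose, path = frontier.popleft()
        if len(path) >= horizon:
            continue
        state = model.state_of_pose(pose)
        for a in MOVES:
            nxt = model.pose_successor(pose, a)
            if nxt is None:
                continue
            npath = path + (a,)
            target = model.state_of_pose(nxt)
            if nxt not in seen:
                # shortest route to a new target state
                seen.add(nxt)
                if target is not None and npath not in emitted:
                    emitted.add(npath)
                    policies.append(Policy(actions=npath, target=target))
                frontier.append((nxt, npath))
            elif (
                state is not None
                and target is not None
                and (state, a) not in model._experienced
                and npath not in emitted
            ):
                # a believed-but-unconfirmed door off the tree: a policy
                # that walks there and crosses it once
                emitted.add(npath)
                policies.append(Policy(actions=npath, target=target))
    return policies


def _dirichlet_update_kl(counts: np.ndarray, idx: np.ndarray, eta: float) -> np.ndarray:
    """KL(Dir(counts + eta * e_i) || Dir(counts)) for each index in idx."""
    total = counts.sum()
    a_i = counts[idx]
    return (
        gammaln(total + eta)
        - gammaln(total)
        - (gammaln(a_i + eta) - gammaln(a_i))
        + eta * (digamma(a_i + eta) - digamma(total + eta))
    )


def _obs_novelty(model: CognitiveModel) -> np.ndarray:
    """A_o Dirichlet-update KL of observing at each state (novelty bonus).

    Evaluated at the most credible color of each state's column, matching
    the maximum-likelihood rollout: averaging over the full predictive
    would be dominated by the huge (but improbable) updates of near-empty
    tail cells and make every state look novel.  Un-visited states with a
    uniform column keep the full novelty of their first observation.
    """
    if model.n_colors == 0:
        return np.zeros(model.n_states)
    idx = np.argmax(model.A_o, axis=0)
    out = np.empty(model.n_states)
    for s in range(model.n_states):
        out[s] = float(_dirichlet_update_kl(model.A_o[:, s], np.array([idx[s]]), model.eta_exp)[0])
    return out


def _trans_novelty(model: CognitiveModel, action: Action) -> np.ndarray:
    """B_s Dirichlet-update KL of taking ``action`` from each state.

    Evaluated at the most credible successor (see :func:`_obs_novelty`);
    an experienced crossing shrinks this bonus by more than an order of
    magnitude, which is what stops the agent re-confirming known doors
    while unconfirmed ones remain.
    """
    counts = model.B_s[:, :, int(action)]
    idx = np.argmax(counts, axis=0)
    out = np.empty(model.n_states)
    for s in range(model.n_states):
        out[s] = float(_dirichlet_update_kl(counts[:, s], np.array([idx[s]]), model.eta_exp)[0])
    return out


def _ml_transition(model: CognitiveModel, action: Action) -> np.ndarray:
    """Maximum-likelihood rollout dynamics: argmax successor per state.

    Scoring a policy with the raw count-mean transitions lets the belief
    diffuse a little at every step (columns are never exactly one-hot),
    and over a 10-14 step horizon that diffusion swamps the epistemic
    terms with phantom mass on far-away states.  The rollout therefore
    follows the most credible successor of each state; the full
    Dirichlet model still supplies all the information-gain terms.
    """
    t = model.transition(action)
    det = np.zeros_like(t)
    det[np.argmax(t, axis=0), np.arange(t.shape[1])] = 1.0
    return det


def expected_free_energy(
    policy: Policy,
    belief: BeliefState,
    model: CognitiveModel,
    pref: Preference,
    horizon: int,
    collision_weight: float = 1.0,
    discount: float = 0.85,
) -> EFERecord:
    """Roll the belief forward through the policy and decompose its EFE.

    Every per-step term is weighted by ``discount**tau``: without a time
    preference a novel door one step away and one eight steps away score
    the same total and the agent churns between far-apart targets.  The discount
    makes nearby epistemic value (and nearby goals) worth more.
    """
    horizon = min(max(horizon, len(policy.actions)), MAX_HORIZON)
    actions = list(policy.actions) + [Action.STAY] * (horizon - len(policy.actions))
    q = belief.padded_to(model.n_states).q_s.copy()
    pose: Pose | None = model.pose_of_state(belief.map_state)
    obs_lik = model.obs_likelihood() if model.n_colors else None
    novelty_o = _obs_novelty(model)
    novelty_b = {a: _trans_novelty(model, a) for a in MOVES}
    log_pref = pref.log_probs(model.colors) if model.n_colors else np.zeros(0)
    rec = EFERecord()
    w = 1.0
    for a in actions:
        a = Action(a)
        risk = 0.0
        ig_b = 0.0
        if a != Action.STAY:
            if pose is not None and (tuple(pose), a) in model.blocked:
                risk = 1.0
            pose = model.pose_successor(pose, a) if pose is not None else None
            ig_b = float(q @ novelty_b[a])
            q = _ml_transition(model, a) @ q
        # predictive observation and the belief shift it would cause
        if obs_lik is not None and obs_lik.size:
            p_o = obs_lik @ q
            post = obs_lik * q[None, :]
            norm = post.sum(axis=1, keepdims=True)
            good = norm[:, 0] > 1e-300
            post[good] = post[good] / norm[good]
            with np.errstate(divide="ignore", invalid="ignore"):
                logr = np.where(post > 0, np.log(np.maximum(post, 1e-300)) - np.log(np.maximum(q[None, :], 1e-300)), 0.0)
            kl_per_o = (post * logr).sum(axis=1)
            ig_state = float(p_o[good] @ kl_per_o[good])
            utility = float(p_o @ log_pref)
        else:
            ig_state = 0.0
            utility = 0.0
        ig_params = float(q @ novelty_o) + ig_b
        rec.info_gain_state.append(w * max(ig_state, 0.0))
        rec.info_gain_params.append(w * max(ig_params, 0.0))
        rec.utility.append(w * utility)
        rec.collision_risk.append(w * collision_weight * risk)
        w *= discount
    return rec


def policy_probabilities(totals: np.ndarray, gamma: float) -> np.ndarray:
    """Tempered softmax over negative EFE: ``sigma(-gamma * G)``."""
    z = -gamma * np.asarray(totals, dtype=float)
    z -= z.max()
    p = np.exp(z)
    return p / p.sum()


def select_action(
    policies: list[Policy],
    records: list[EFERecord],
    gamma: float,
    rng: np.random.Generator,
) -> tuple[Policy, np.ndarray]:
    """Sample a policy from the tempered softmax; execute its first action."""
    if not policies:
        raise ValueError("need at least one candidate policy")
    totals = np.array([r.total for r in records])
    probs = policy_probabilities(totals, gamma)
    idx = int(rng.choice(len(policies), p=probs))
    return policies[idx], probs
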