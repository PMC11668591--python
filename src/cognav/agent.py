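"""The perception–learning–planning–action cycle.

Each step runs, in order: perceive the floor color and collision flags;
grow the observation support if the color is novel; update the state
posterior and the confidence mode; then — only while confident —
unlearn contradicted passages, expand the map over the predicted
outcomes of every visible door, and reinforce the experienced
transition; finally score candidate policies by expected free energy,
sample one through the tempered softmax and execute its first action.
Only the first action of the sampled policy is ever executed: the agent
re-plans every step, which is what lets it re-map on the spot when the
world changes under it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .actions import Action, MOVES
from .generative_model import CognitiveModel, Preference
from .inference import (
    BeliefState,
    MODE_LOST,
    MODE_NORMAL,
    check_confidence,
    compute_vfe,
    initial_belief,
    update_belief,
)
from .planning import EFERecord, Policy, enumerate_policies, expected_free_energy, select_action
from .room_world import RoomLayout, StepResult, WorldPose, step as world_step
from .structure_learning import (
    GrowthEvent,
    imagine_frontier,
    learn_from_transition,
    map_confidence,
    negative_update,
)


@dataclass(frozen=True)
class AgentConfig:
    """Tunable parameters of the agent (all config-exposed)."""

    eps: float = 0.025
    eta_exp: float = 1.0
    eta_im: float = 0.1
    eta_neg: float = 1.0
    gamma: float = 8.0
    horizon: int = 10
    collision_weight: float = 2.0
    certainty_threshold: float = 0.5
    recovery_threshold: float = 0.7

    def model_kwargs(self) -> dict:
        return dict(eps=self.eps, eta_exp=self.eta_exp, eta_im=self.eta_im, eta_neg=self.eta_neg)


@dataclass
class StepRecord:
    """One line of the run log."""

    step: int
    action: str
    observation: str
    moved: bool
    world_pose: tuple[int, int]
    internal_pose: tuple[int, int]
    confidence: float
    entropy: float
    mode: str
    dims: tuple[int, int, int]
    n_candidates: int
    chosen_target: int | None
    efe_total: float
    vfe: float
    events: list[str] = field(default_factory=list)


@dataclass
class RunLog:
    records: list[StepRecord] = field(default_factory=list)

    def append(self, rec: StepRecord) -> None:
        self.records.append(rec)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(json.dumps(asdict(r)) + "\n")

    @property
    def n_steps(self) -> int:
        return len(self.records)


class Agent:
    """Active-inference navigator with a growing cognitive map."""

    def __init__(
        self,
        config: AgentConfig | None = None,
        pref: Preference | None = None,
        seed: int | np.random.Generator = 0,
    ):
        self.config = config or AgentConfig()
        self.pref = pref or Preference()
        self.rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        self.model = CognitiveModel.initial(origin=(0, 0), **self.config.model_kwargs())
        self.belief = initial_belief(self.model, origin=(0, 0))
        self.last_action: Action = Action.STAY
        self.visited_states: set[int] = {0}
        self.last_events: list[str] = []
        self.last_vfe: float = 0.0
        self.last_policies: list[Policy] = []
        self.last_records: list[EFERecord] = []
        self.last_probs: np.ndarray | None = None

    # -- perception / learning ----------------------------------------
    def perceive(self, obs: StepResult) -> None:
        """Phases 1-4 of the cycle for one observation."""
        cfg = self.config
        events: list[str] = []
        novel_color = obs.observation not in self.model.colors
        if novel_color:
            self.model.grow_color(obs.observation)
            events.append(f"color:{obs.observation}")
        prev_belief = self.belief
        belief = update_belief(
            prev_belief, self.model, self.last_action, obs, cfg.certainty_threshold,
            novel_color=novel_color,
        )
        went_lost = belief.mode == MODE_LOST
        belief = check_confidence(belief, self.model, cfg.certainty_threshold, cfg.recovery_threshold)
        self.last_vfe = compute_vfe(prev_belief, belief, self.model, self.last_action, obs)
        if belief.mode == MODE_NORMAL and belief.confidence >= cfg.recovery_threshold:
            # All model writes require a solidly localized agent: updating
            # at middling confidence writes transitions into half-wrong
            # states and corrupts the map.  Negative learning runs first:
            # contradiction detection must see the pre-update beliefs
            # about which sides are open.
            for i, d in enumerate(MOVES):
                if obs.collisions[i]:
                    ev = negative_update(self.model, belief, d)
                    if ev is not None:
                        events.append(ev.detail)
            for ev in imagine_frontier(belief, self.model, obs):
                events.append(f"{ev.kind}:{ev.detail}")
            s_now = belief.map_state
            # No transition learning on a step that passed through lost
            # mode: the previous state estimate cannot be trusted after a
            # suspected relocation, even if confidence recovered at once.
            conf_ok = (
                not went_lost
                and prev_belief.mode == MODE_NORMAL
                and prev_belief.confidence >= cfg.recovery_threshold
            )
            if conf_ok:
                learn_from_transition(
                    self.model, prev_belief.map_state, self.last_action, s_now, obs.observation
                )
            self.visited_states.add(s_now)
        self.belief = belief.padded_to(self.model.n_states)
        self.last_events = events

    # -- planning ------------------------------------------------------
    def plan(self) -> Action:
        cfg = self.config
        policies = enumerate_policies(self.belief, self.model, cfg.horizon)
        records = [
            expected_free_energy(
                p, self.belief, self.model, self.pref, cfg.horizon, cfg.collision_weight
            )
            for p in policies
        ]
        chosen, probs = select_action(policies, records, cfg.gamma, self.rng)
        self.last_policies = policies
        self.last_records = records
        self.last_probs = probs
        self.last_choice = chosen
        return chosen.actions[0]


@dataclass
class EpisodeResult:
    outcome: str  # "learned" | "goal" | "budget"
    steps: int
    log: RunLog
    agent: Agent

    @property
    def success(self) -> bool:
        return self.outcome != "budget"


def run_episode(
    layout: RoomLayout,
    start: WorldPose,
    termination: str,
    config: AgentConfig | None = None,
    pref: Preference | None = None,
    seed: int | np.random.Generator = 0,
    max_steps: int = 500,
    agent: Agent | None = None,
    map_origin: WorldPose | None = None,
) -> EpisodeResult:
    """Run one seeded episode until the termination condition.

    ``termination`` is ``"explore"`` (stop when the believed transition
    structure matches the ground truth with min confidence 0.6 — the
    map-learned flag), ``"goal"`` (stop when the agent chooses to Stay in
    a room of the preferred color; the terminal Stay is not counted), or
    ``"budget"`` (run for ``max_steps``).  Passing an existing ``agent``
    continues with its memory, e.g. after a kidnapping; ``map_origin``
    then names the world room its internal origin refers to.
    """
    if termination not in ("explore", "goal", "budget"):
        raise ValueError(f"unknown termination {termination!r}")
    if agent is None:
        agent = Agent(config=config, pref=pref, seed=seed)
    elif pref is not None:
        agent.pref = pref
    origin = map_origin if map_origin is not None else start
    log = RunLog()
    pose = start
    _, obs = world_step(layout, pose, Action.STAY)
    for t in range(max_steps + 1):
        agent.perceive(obs)
        if termination == "explore":
            _, passed, _ = map_confidence(agent.model, layout, origin)
            if passed:
                return EpisodeResult("learned", t, log, agent)
        if t >= max_steps:
            break
        action = agent.plan()
        if (
            termination == "goal"
            and action == Action.STAY
            and agent.pref.target is not None
            and layout.color_at(pose) == agent.pref.target
        ):
            return EpisodeResult("goal", t, log, agent)
        new_pose, new_obs = world_step(layout, pose, action)
        log.append(
            StepRecord(
                step=t,
                action=Action(action).name,
                observation=obs.observation,
                moved=new_obs.moved,
                world_pose=new_pose.as_tuple(),
                internal_pose=tuple(agent.belief.pose),
                confidence=agent.belief.confidence,
                entropy=agent.belief.entropy,
                mode=agent.belief.mode,
                dims=agent.model.dims(),
                n_candidates=len(agent.last_policies),
                chosen_target=agent.last_choice.target,
                efe_total=float(agent.last_records[agent.last_policies.index(agent.last_choice)].total),
                vfe=agent.last_vfe,
                events=list(agent.last_events),
            )
        )
        agent.last_action = Action(action)
        pose, obs = new_pose, new_obs
    return EpisodeResult("budget", log.n_steps, log, agent)
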