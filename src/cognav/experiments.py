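"""End-to-end behavioral experiment protocols.

Four families, mirroring how the agent is evaluated: pure exploration
(steps until the believed map matches the true transition structure),
goal seeking with and without a previously learned map, the Tolman
detour protocol (three routes, movable blockage, periodic silent
kidnapping back to the start), and Donut re-mapping (a learned short
path sealed off mid-run).  Every suite is reproducible from its seed:
per-run seeds are spawned from a single ``numpy`` SeedSequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .actions import Action
from .agent import Agent, AgentConfig, EpisodeResult, run_episode
from .generative_model import Preference
from .oracle import min_coverage_steps, shortest_path_steps
from .room_world import RoomLayout, WorldPose, add_obstacle, load_fixture, seal_room, step as world_step


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _discovery_steps(layout: RoomLayout, start: WorldPose, result: EpisodeResult) -> int | None:
    """First step count at which every room had been visited (Fig-7 metric)."""
    rooms = set(layout.rooms())
    seen = {start.as_tuple()}
    if seen == rooms:
        return 0
    for rec in result.log.records:
        seen.add(tuple(rec.world_pose))
        if seen >= rooms:
            return rec.step + 1
    return None


# ---------------------------------------------------------------------
# Exploration
# ---------------------------------------------------------------------

def run_exploration_suite(
    env: str,
    n_runs: int = 20,
    seed: int = 0,
    config: AgentConfig | None = None,
    max_steps: int = 400,
) -> tuple[pd.DataFrame, dict]:
    """Seeded pure-exploration runs (uniform preference, w = 0).

    Returns a per-run table and a summary with mean ± sd steps-to-learn,
    mean steps to first discover all rooms, and the oracle bound for the
    starts used.  Runs that exhaust the budget are flagged and excluded
    from the means.
    """
    layout = load_fixture(env) if isinstance(env, str) else env
    config = config or AgentConfig()
    seeds = _spawn_seeds(seed, n_runs)
    rows = []
    for i, s in enumerate(seeds):
        rng = np.random.default_rng(s)
        start = WorldPose(*layout.starts[int(rng.integers(len(layout.starts)))])
        res = run_episode(
            layout, start, "explore", config=config, pref=Preference(), seed=rng, max_steps=max_steps
        )
        oracle = min_coverage_steps(layout, start)
        rows.append(
            dict(
                run=i,
                seed=s,
                start=start.as_tuple(),
                steps=res.steps,
                outcome=res.outcome,
                discovery_steps=_discovery_steps(layout, start, res),
                oracle=oracle,
                final_states=res.agent.model.n_states,
            )
        )
    table = pd.DataFrame(rows)
    ok = table[table.outcome == "learned"]
    summary = dict(
        env=layout.name,
        n_runs=n_runs,
        n_failed=int((table.outcome != "learned").sum()),
        mean_steps=float(ok.steps.mean()),
        sd_steps=float(ok.steps.std(ddof=1)) if len(ok) > 1 else 0.0,
        mean_discovery=float(ok.discovery_steps.mean()),
        oracle_mean=float(table.oracle.mean()),
        all_runs_ge_oracle=bool((ok.steps >= ok.oracle).all()),
    )
    return table, summary


# ---------------------------------------------------------------------
# Goal seeking
# ---------------------------------------------------------------------

def run_goal_suite(
    env: str,
    goal_color: str | None = None,
    with_prior: bool = True,
    n_runs: int = 20,
    seed: int = 0,
    config: AgentConfig | None = None,
    utility_weight: float = 2.0,
    max_steps: int = 400,
) -> tuple[pd.DataFrame, dict]:
    """Navigate to a preferred floor color, with or without a learned map.

    With prior: the agent first explores, is then silently relocated to a
    random room and must reach the goal; steps are compared to the
    shortest-path oracle from the relocation point.  Success requires the
    agent to *choose to stay* at the goal.
    """
    layout = load_fixture(env) if isinstance(env, str) else env
    goal = goal_color or layout.goal_color
    if goal is None or goal not in layout.colors():
        raise ValueError(f"goal color {goal!r} not present in {layout.name}")
    config = config or AgentConfig()
    pref = Preference(target=goal, weight=utility_weight)
    seeds = _spawn_seeds(seed, n_runs)
    rows = []
    for i, s in enumerate(seeds):
        rng = np.random.default_rng(s)
        start = WorldPose(*layout.starts[int(rng.integers(len(layout.starts)))])
        agent = None
        map_origin = start
        pose = start
        if with_prior:
            explored = run_episode(
                layout, start, "explore", config=config, pref=Preference(), seed=rng, max_steps=max_steps
            )
            agent = explored.agent
            rooms = layout.rooms()
            pose = WorldPose(*rooms[int(rng.integers(len(rooms)))])
        else:
            agent = Agent(config=config, pref=pref, seed=rng)
        res = run_episode(
            layout,
            pose,
            "goal",
            config=config,
            pref=pref,
            seed=rng,
            max_steps=max_steps,
            agent=agent,
            map_origin=map_origin,
        )
        rows.append(
            dict(
                run=i,
                seed=s,
                start=pose.as_tuple(),
                steps=res.steps,
                outcome=res.outcome,
                oracle=shortest_path_steps(layout, pose, goal),
            )
        )
    table = pd.DataFrame(rows)
    ok = table[table.outcome == "goal"]
    summary = dict(
        env=layout.name,
        goal=goal,
        with_prior=with_prior,
        n_runs=n_runs,
        n_failed=int((table.outcome != "goal").sum()),
        mean_steps=float(ok.steps.mean()) if len(ok) else float("nan"),
        mean_oracle=float(ok.oracle.mean()) if len(ok) else float("nan"),
        mean_excess=float((ok.steps - ok.oracle).mean()) if len(ok) else float("nan"),
    )
    return table, summary


# ---------------------------------------------------------------------
# Tolman detour protocol
# ---------------------------------------------------------------------

#: Rooms unique to each route in the Tolman fixture; a completion is
#: classified by the last distinguishing room visited before the goal.
TOLMAN_MARKERS = {
    1: {(3, 2), (3, 3)},
    2: {(1, 1), (1, 2), (1, 3), (1, 4)},
    3: {(6, 1), (6, 2), (6, 3), (6, 4), (6, 5)},
}
TOLMAN_BLOCKS = {"A": (WorldPose(3, 2), Action.NORTH), "B": (WorldPose(3, 4), Action.NORTH)}
#: Rooms from which each blockage is perceivable (adjacent contact).
_BLOCK_CONTACT = {"A": {(3, 2), (3, 3)}, "B": {(3, 4), (3, 5)}}


@dataclass
class TolmanSeriesResult:
    obstacle: str | None
    route_counts: dict[int, int] = field(default_factory=lambda: {1: 0, 2: 0, 3: 0})
    runs: int = 0
    completions: int = 0


def _classify_route(trace: list[tuple[int, int]]) -> int | None:
    last = {r: -1 for r in TOLMAN_MARKERS}
    for i, pose in enumerate(trace):
        for r, marks in TOLMAN_MARKERS.items():
            if pose in marks:
                last[r] = i
    best = max(last, key=lambda r: last[r])
    return best if last[best] >= 0 else None


def run_tolman_protocol(
    n_agents: int = 10,
    runs_per_series: int = 12,
    kidnap_every: int = 20,
    utility_weight: float = 2.0,
    horizon: int = 14,
    gamma: float = 4.0,
    seed: int = 0,
    config: AgentConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, TolmanSeriesResult]]:
    """Three series of runs per agent: no obstacle, block at A, block at B.

    Agents keep their memory across runs and series.  Every run starts at
    the bottom of the maze; a run ends when the agent chooses to stay at
    the red goal or after ``kidnap_every`` steps, after which the agent
    is silently repositioned at the start.  For the obstacle series,
    completions are counted from the first step at which the agent was in
    contact with the blockage.
    """
    base = load_fixture("Tolman")
    if config is None:
        config = AgentConfig(gamma=gamma, horizon=horizon)
    pref = Preference(target="red", weight=utility_weight)
    start = WorldPose(*base.starts[0])
    seeds = _spawn_seeds(seed, n_agents)
    series_defs = [None, "A", "B"]
    results = {str(s): TolmanSeriesResult(obstacle=s) for s in series_defs}
    rows = []
    for a_idx, s in enumerate(seeds):
        agent = Agent(config=config, pref=pref, seed=s)
        for series in series_defs:
            layout = base if series is None else add_obstacle(base, *TOLMAN_BLOCKS[series])
            res = results[str(series)]
            counting = series is None  # obstacle series count after first contact
            for run in range(runs_per_series):
                pose = start
                trace: list[tuple[int, int]] = [pose.as_tuple()]
                _, obs = world_step(layout, pose, Action.STAY)
                completed_route: int | None = None
                for t in range(kidnap_every):
                    agent.perceive(obs)
                    if not counting and pose.as_tuple() in _BLOCK_CONTACT[series]:
                        counting = True
                    action = agent.plan()
                    if action == Action.STAY and layout.color_at(pose) == "red":
                        completed_route = _classify_route(trace)
                        break
                    pose, obs = world_step(layout, pose, action)
                    agent.last_action = Action(action)
                    trace.append(pose.as_tuple())
                res.runs += 1
                if completed_route is not None and counting:
                    res.completions += 1
                    res.route_counts[completed_route] += 1
                rows.append(
                    dict(
                        agent=a_idx,
                        series=str(series),
                        run=run,
                        completed=completed_route is not None,
                        route=completed_route,
                        counted=bool(completed_route is not None and counting),
                        steps=len(trace) - 1,
                    )
                )
                # silent repositioning to the start for the next run
                agent.last_action = Action.STAY
    return pd.DataFrame(rows), results


# ---------------------------------------------------------------------
# Donut re-mapping
# ---------------------------------------------------------------------

@dataclass
class DonutResult:
    verdict: bool
    goal_reached: bool
    bumps: int
    steps: int
    negative_events: int


def run_donut_remapping(
    seed: int = 0,
    config: AgentConfig | None = None,
    negative_learning: bool = True,
    seal_at: int = 2,
    bump_budget: int = 4,
    max_steps: int = 80,
) -> DonutResult:
    """Learn the Donut, get kidnapped to a corner, chase the pink room
    while the short path is sealed off mid-run.

    The verdict passes when the goal is reached via the long path with at
    most ``bump_budget`` collisions against the sealed room.  With
    negative learning disabled the agent keeps believing the sealed
    passage open and fails.
    """
    layout = load_fixture("Donuts")
    config = config or AgentConfig()
    rng = np.random.default_rng(seed)
    rooms = layout.rooms()
    start = WorldPose(*rooms[int(rng.integers(len(rooms)))])
    explored = run_episode(layout, start, "explore", config=config, seed=rng, max_steps=400)
    agent = explored.agent
    agent.model.negative_learning = negative_learning
    agent.pref = Preference(target="pink", weight=2.0)
    sealed_layout = seal_room(layout, WorldPose(1, 3))
    pose = WorldPose(0, 0)  # kidnapped to a corner, agent not informed
    cur = layout
    _, obs = world_step(cur, pose, Action.STAY)
    bumps = 0
    neg_events = 0
    goal_reached = False
    steps = 0
    for t in range(max_steps):
        agent.perceive(obs)
        neg_events += sum(1 for e in agent.last_events if "->" in e)
        if t == seal_at:
            cur = sealed_layout
        action = agent.plan()
        if action == Action.STAY and cur.color_at(pose) == "pink":
            goal_reached = True
            break
        new_pose, obs = world_step(cur, pose, action)
        if action != Action.STAY and not obs.moved:
            # count only collisions against the sealed room's sides
            from .actions import DELTA

            d = DELTA[Action(action)]
            if (pose.x + d[0], pose.y + d[1]) == (1, 3):
                bumps += 1
        pose = new_pose
        agent.last_action = Action(action)
        steps = t + 1
    verdict = goal_reached and bumps <= bump_budget
    return DonutResult(verdict, goal_reached, bumps, steps, neg_events)
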