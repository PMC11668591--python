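"""Growth of the cognitive map over predicted, un-visited locations.

This is the heart of the approach: instead of creating a state only when
a new room is physically entered, the agent expands its model over every
door it can *see* from the room it occupies.  Each open side of the
current room yields a predicted pose; if that pose is new, the position
support grows, and if no state is bound to it yet, a fresh state is
created with a uniform observation column and tied to the pose.  Weak
("imagined") transition counts connect the current state to these
predicted ones, so planning can reason over rooms that have never been
observed.  Experienced transitions are later reinforced at a higher
learning rate, keeping imagined links strictly weaker than experienced
ones, and collisions that contradict a believed-open passage trigger
negative learning that re-routes the transition mass to a
self-transition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .actions import Action, DELTA, MOVES, opposite
from .generative_model import CognitiveModel, Pose
from .inference import BeliefState, MODE_NORMAL
from .room_world import RoomLayout, StepResult, WorldPose


@dataclass(frozen=True)
class GrowthEvent:
    """One model-dimension change, for the run log."""

    kind: str  # "color" | "pose" | "state" | "negative"
    detail: str
    dims: tuple[int, int, int]


def imagine_frontier(
    belief: BeliefState, model: CognitiveModel, obs: StepResult
) -> list[GrowthEvent]:
    """Expand the model over the predicted outcomes of every direction.

    Must only be called in normal mode (expansion pauses while lost).
    Blocked sides add a weak self-transition and suppress the pose edge;
    open sides create/link the predicted neighbor state.  Each (state,
    direction) is counted once — re-imagining is idempotent.
    """
    if belief.mode != MODE_NORMAL:
        raise ValueError("frontier expansion is paused while the agent is lost")
    events: list[GrowthEvent] = []
    s = belief.map_state
    pose = tuple(belief.pose)
    for i, d in enumerate(MOVES):
        if obs.collisions[i]:
            believed_open = model.B_p.get((pose, d)) is not None
            if believed_open and not model.negative_learning:
                # ablated: the contradiction is ignored outright
                continue
            model.blocked.add((pose, d))
            if (s, d) not in model._imagined:
                model.B_s[s, s, int(d)] += model.eta_im
                model._imagined.add((s, d))
            continue
        # An open side: clear any stale collision evidence (a removed
        # obstacle), predict the neighbor pose and make sure a state
        # exists for it.
        model.blocked.discard((pose, d))
        dx, dy = DELTA[d]
        p2 = (pose[0] + dx, pose[1] + dy)
        if p2 not in model.poses:
            model.grow_pose(p2)
            events.append(GrowthEvent("pose", f"{p2}", model.dims()))
        model.record_pose_transition(pose, d, p2)
        model.record_pose_transition(p2, opposite(d), pose)
        s2 = model.state_of_pose(p2)
        if s2 is None:
            s2 = model.grow_state()
            model.bind_pose_to_state(p2, s2)
            events.append(GrowthEvent("state", f"{s2}@{p2}", model.dims()))
        if (s, d) not in model._imagined:
            model.B_s[s2, s, int(d)] += model.eta_im
            # A weak reverse prior lets planning route back through the
            # imagined state without asserting the return door.
            model.B_s[s, s2, int(opposite(d))] += model.eta_im / 2.0
            model._imagined.add((s, d))
    return events


def learn_from_transition(
    model: CognitiveModel,
    s_prev: int,
    action: Action,
    s_now: int,
    color: str,
) -> None:
    """Dirichlet update from one experienced, confidently inferred step.

    The crossed transition is reinforced in both directions (experience
    confirms bi-directionality) and the observed color is credited to
    the current state, all at the experienced learning rate.
    """
    action = Action(action)
    model.A_o[model.color_index(color), s_now] += model.eta_exp
    if action != Action.STAY and s_now != s_prev:
        model.B_s[s_now, s_prev, int(action)] += model.eta_exp
        model.B_s[s_prev, s_now, int(opposite(action))] += model.eta_exp
        model._experienced.add((s_prev, action))
        model._experienced.add((s_now, opposite(action)))
    elif action != Action.STAY and model.negative_learning:
        # Attempted move that did not change rooms: an experienced
        # self-transition.  This is collision evidence, so it is covered
        # by the negative-learning ablation switch.
        model.B_s[s_prev, s_prev, int(action)] += model.eta_exp
        model._experienced.add((s_prev, action))


def negative_update(model: CognitiveModel, belief: BeliefState, action: Action) -> GrowthEvent | None:
    """Unlearn a believed-open passage contradicted by a collision.

    The transition count toward the believed neighbor is reduced by
    ``eta_neg`` (floored at the base pseudo-count) and the removed mass
    re-routed to the self-transition; the pose edge is suppressed so
    plans stop using it.  Returns the logged event, or None if the model
    held no belief to contradict.
    """
    if not model.negative_learning:
        return None
    action = Action(action)
    s = belief.map_state
    pose = tuple(belief.pose)
    nxt = model.pose_successor(pose, action)
    if nxt is None:
        return None
    s2 = model.state_of_pose(nxt)
    model.blocked.add((pose, action))
    if s2 is None or s2 == s:
        return None
    old = model.B_s[s2, s, int(action)]
    new = max(model.eps, old - model.eta_neg)
    model.B_s[s2, s, int(action)] = new
    model.B_s[s, s, int(action)] += old - new
    return GrowthEvent("negative", f"{s}-{action.name}->{s2}", model.dims())


def map_confidence(
    model: CognitiveModel, layout: RoomLayout, start: WorldPose
) -> tuple[float, bool, int]:
    """Minimum believed probability over all true door transitions.

    The internal pose frame has its origin at the exploration start, so
    each true room corresponds to the internal pose offset from
    ``start`` (a test-harness correspondence; the agent never sees it).
    Returns ``(min_prob, passed, missing_rooms)``; the flag passes when
    every room has a state and the minimum is at least 0.6.
    """
    trans = {a: model.transition(a) for a in MOVES}
    missing = 0
    min_prob = 1.0
    for (x, y) in layout.rooms():
        p = (x - start.x, y - start.y)
        s = model.state_of_pose(p)
        if s is None:
            missing += 1
            continue
        for a in MOVES:
            if not layout.has_door(WorldPose(x, y), a):
                continue
            dx, dy = DELTA[a]
            s2 = model.state_of_pose((p[0] + dx, p[1] + dy))
            if s2 is None:
                missing += 1
                continue
            min_prob = min(min_prob, float(trans[a][s2, s]))
    if missing:
        return 0.0, False, missing
    return min_prob, min_prob >= 0.6, 0
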