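"""Exact ground-truth baselines: minimum coverage walks and shortest paths.

These define the lower bounds the agent is judged against.  The coverage
oracle is an exact search over (room, visited-set) states — equivalent in
result to an admissible A* but with no heuristic, which is tractable for
mazes of a couple dozen rooms and gives the exactness the acceptance
checks need.
"""

from __future__ import annotations

from collections import deque
from typing import Callable

from .room_world import RoomLayout, WorldPose


def min_coverage_steps(layout: RoomLayout, start: WorldPose) -> int:
    """Exact minimum number of door-crossing moves to visit every room once.

    Breadth-first search over (room, visited-set) states; each edge of the
    search is one executed move, so BFS depth is the answer.
    """
    rooms = layout.rooms()
    index = {xy: i for i, xy in enumerate(rooms)}
    s = start.as_tuple()
    if s not in index:
        raise ValueError(f"start {start} is not a room")
    full = (1 << len(rooms)) - 1
    init = (s, 1 << index[s])
    if init[1] == full:
        return 0
    seen = {init}
    frontier = deque([init])
    steps = 0
    while frontier:
        steps += 1
        for _ in range(len(frontier)):
            cur, mask = frontier.popleft()
            for nb in layout.neighbors(cur):
                nmask = mask | (1 << index[nb])
                if nmask == full:
                    return steps
                state = (nb, nmask)
                if state not in seen:
                    seen.add(state)
                    frontier.append(state)
    raise ValueError("layout is not connected: some rooms are unreachable")


def mean_coverage_steps(layout: RoomLayout, starts: list[tuple[int, int]] | None = None) -> float:
    """Coverage oracle averaged over start poses (layout starts by default)."""
    poses = starts if starts is not None else layout.starts
    if not poses:
        poses = layout.rooms()
    vals = [min_coverage_steps(layout, WorldPose(*p)) for p in poses]
    return sum(vals) / len(vals)


def shortest_path_steps(
    layout: RoomLayout,
    start: WorldPose,
    goal: Callable[[tuple[int, int]], bool] | str,
) -> int:
    """Length of the shortest door-path from ``start`` to any satisfying room.

    ``goal`` is either a predicate over room coordinates or a color token
    (reach any room of that color).
    """
    if isinstance(goal, str):
        target_color = goal
        pred = lambda xy: layout.color[xy] == target_color  # noqa: E731
    else:
        pred = goal
    s = start.as_tuple()
    if not layout.is_room(*s):
        raise ValueError(f"start {start} is not a room")
    if pred(s):
        return 0
    seen = {s}
    frontier = deque([s])
    steps = 0
    while frontier:
        steps += 1
        for _ in range(len(frontier)):
            cur = frontier.popleft()
            for nb in layout.neighbors(cur):
                if nb in seen:
                    continue
                if pred(nb):
                    return steps
                seen.add(nb)
                frontier.append(nb)
    raise ValueError("no satisfying room is reachable from the start")
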