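"""Cardinal actions shared by the world simulator and the agent.

The agent can move one room in the four cardinal directions or remain
stationary.  Coordinates are 0-based with x increasing East and y
increasing North, so ``NORTH`` adds ``(0, 1)`` to a pose.
"""

from __future__ import annotations

from enum import IntEnum


class Action(IntEnum):
    NORTH = 0
    EAST = 1
    SOUTH = 2
    WEST = 3
    STAY = 4


#: Pose increment for each action, (dx, dy).
DELTA: dict[Action, tuple[int, int]] = {
    Action.NORTH: (0, 1),
    Action.EAST: (1, 0),
    Action.SOUTH: (0, -1),
    Action.WEST: (-1, 0),
    Action.STAY: (0, 0),
}

#: The four movement actions, in index order.
MOVES: tuple[Action, ...] = (Action.NORTH, Action.EAST, Action.SOUTH, Action.WEST)

_OPPOSITE = {
    Action.NORTH: Action.SOUTH,
    Action.SOUTH: Action.NORTH,
    Action.EAST: Action.WEST,
    Action.WEST: Action.EAST,
    Action.STAY: Action.STAY,
}

N_ACTIONS = len(Action)


def opposite(action: Action) -> Action:
    """Return the reverse movement (``STAY`` is its own reverse)."""
    return _OPPOSITE[Action(action)]
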