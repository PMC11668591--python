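"""Ground-truth simulator of room-structured mini-grid mazes.

A maze is a rectangular grid of rooms.  Each room has a floor color (the
only visual observation the agent ever receives) and a door-or-wall flag
on each of its four sides.  Moving through a door changes rooms; moving
into a wall leaves the pose unchanged.  The agent additionally perceives,
for the room it currently occupies, which of the four sides are blocked
("expected risk of collision") — obstacles are never sensed remotely.

Non-rectangular mazes (T-shape, donut, Tolman) are embedded in the grid
with *void* cells (color token ``.``), which are not rooms: every side
facing a void cell is a wall and void cells are excluded from the
connectivity requirement.

Layout documents are small YAML files with a color grid and two gate
grids (doors between horizontal and vertical neighbors); rows are listed
from North (top) to South.  See ``cognav/layouts/`` for the packaged
environments.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .actions import Action, DELTA, MOVES, opposite

VOID = "."


class LayoutError(ValueError):
    """Raised for layout documents violating the format or its invariants."""


@dataclass(frozen=True)
class WorldPose:
    """Ground-truth room coordinates, 0-based, x East / y North."""

    x: int
    y: int

    def __add__(self, delta: tuple[int, int]) -> "WorldPose":
        return WorldPose(self.x + delta[0], self.y + delta[1])

    def as_tuple(self) -> tuple[int, int]:
        return (self.x, self.y)


@dataclass(frozen=True)
class StepResult:
    """What the agent perceives after acting.

    ``collisions`` holds one flag per movement direction (N, E, S, W
    order) for the *resulting* room; a set flag means that side is
    blocked by a wall, void, or the grid boundary.
    """

    observation: str
    collisions: tuple[bool, bool, bool, bool]
    moved: bool


@dataclass
class RoomLayout:
    """Grid of colored rooms with per-side door/wall flags.

    ``east_door[(x, y)]`` is True iff there is a door between rooms
    (x, y) and (x+1, y); ``north_door[(x, y)]`` likewise toward (x, y+1).
    Sides without an entry (boundary, void neighbor) are walls.
    """

    name: str
    width: int
    height: int
    color: dict[tuple[int, int], str]
    east_door: dict[tuple[int, int], bool]
    north_door: dict[tuple[int, int], bool]
    starts: list[tuple[int, int]] = field(default_factory=list)
    goal_color: str | None = None

    # -- basic queries -------------------------------------------------
    def in_bounds(self, x: int, y: int) -> bool:
        return 0 <= x < self.width and 0 <= y < self.height

    def is_room(self, x: int, y: int) -> bool:
        return self.in_bounds(x, y) and self.color.get((x, y), VOID) != VOID

    def rooms(self) -> list[tuple[int, int]]:
        return sorted(xy for xy, c in self.color.items() if c != VOID)

    def n_rooms(self) -> int:
        return len(self.rooms())

    def color_at(self, pose: WorldPose) -> str:
        return self.color[pose.as_tuple()]

    def colors(self) -> set[str]:
        return {c for c in self.color.values() if c != VOID}

    def has_door(self, pose: WorldPose, action: Action) -> bool:
        """Is the side of ``pose`` in direction ``action`` a door?"""
        x, y = pose.x, pose.y
        if action == Action.NORTH:
            return self.north_door.get((x, y), False)
        if action == Action.SOUTH:
            return self.north_door.get((x, y - 1), False)
        if action == Action.EAST:
            return self.east_door.get((x, y), False)
        if action == Action.WEST:
            return self.east_door.get((x - 1, y), False)
        return False

    def collisions_at(self, pose: WorldPose) -> tuple[bool, bool, bool, bool]:
        return tuple(not self.has_door(pose, a) for a in MOVES)  # type: ignore[return-value]

    def neighbors(self, xy: tuple[int, int]) -> list[tuple[int, int]]:
        pose = WorldPose(*xy)
        out = []
        for a in MOVES:
            if self.has_door(pose, a):
                d = DELTA[a]
                out.append((xy[0] + d[0], xy[1] + d[1]))
        return out

    # -- validation ----------------------------------------------------
    def validate(self, allow_sealed: bool = False) -> None:
        """Check the layout invariants; raise :class:`LayoutError` if broken.

        With ``allow_sealed`` a room whose four sides are all walls (the
        Donut "closed room" obstacle) is exempt from the connectivity
        requirement; base layouts are always fully connected.
        """
        for (x, y) in self.east_door:
            if self.east_door[(x, y)]:
                if not (self.is_room(x, y) and self.is_room(x + 1, y)):
                    raise LayoutError(f"door into void/boundary at East side of {(x, y)}")
        for (x, y) in self.north_door:
            if self.north_door[(x, y)]:
                if not (self.is_room(x, y) and self.is_room(x, y + 1)):
                    raise LayoutError(f"door into void/boundary at North side of {(x, y)}")
        rooms = self.rooms()
        if not rooms:
            raise LayoutError("layout has no rooms")
        for s in self.starts:
            if not self.is_room(*s):
                raise LayoutError(f"start {s} is not a room")
        if allow_sealed:
            open_rooms = [
                r for r in rooms if not all(self.collisions_at(WorldPose(*r)))
            ]
        else:
            open_rooms = rooms
        if open_rooms:
            seen = {open_rooms[0]}
            stack = [open_rooms[0]]
            while stack:
                cur = stack.pop()
                for nb in self.neighbors(cur):
                    if nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            missing = set(open_rooms) - seen
            if missing:
                raise LayoutError(f"rooms not reachable through doors: {sorted(missing)}")


# ---------------------------------------------------------------------
# Layout document reader / writer
# ---------------------------------------------------------------------

def _parse_grid(rows: list[str], width: int, what: str) -> list[list[str]]:
    grid = []
    for row in rows:
        toks = row.split()
        if len(toks) != width:
            raise LayoutError(f"{what}: expected {width} tokens per row, got {len(toks)!r} in {row!r}")
        grid.append(toks)
    return grid


def load_layout(text: str) -> RoomLayout:
    """Parse a layout document and validate all invariants."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # pragma: no cover - yaml details
        raise LayoutError(f"not valid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise LayoutError("layout document must be a mapping")
    for key in ("colors", "east_doors", "north_doors"):
        if key not in doc:
            raise LayoutError(f"missing required section {key!r}")

    color_rows = doc["colors"]
    height = len(color_rows)
    width = len(color_rows[0].split())
    cgrid = _parse_grid(color_rows, width, "colors")

    color: dict[tuple[int, int], str] = {}
    for i, row in enumerate(cgrid):
        y = height - 1 - i  # documents list the North row first
        for x, tok in enumerate(row):
            color[(x, y)] = tok

    def gate(tok: str) -> bool:
        if tok in ("door", "1"):
            return True
        if tok in ("wall", "0"):
            return False
        raise LayoutError(f"unknown gate token {tok!r} (expected door|wall|1|0)")

    east_door: dict[tuple[int, int], bool] = {}
    erows = _parse_grid(doc["east_doors"], width - 1, "east_doors") if width > 1 else []
    if width > 1 and len(erows) != height:
        raise LayoutError("east_doors must have one row per grid row")
    for i, row in enumerate(erows):
        y = height - 1 - i
        for x, tok in enumerate(row):
            east_door[(x, y)] = gate(tok)

    north_door: dict[tuple[int, int], bool] = {}
    nrows = _parse_grid(doc["north_doors"], width, "north_doors") if height > 1 else []
    if height > 1 and len(nrows) != height - 1:
        raise LayoutError("north_doors must have height-1 rows")
    for i, row in enumerate(nrows):
        y = height - 2 - i  # row i sits between grid rows i and i+1
        for x, tok in enumerate(row):
            north_door[(x, y)] = gate(tok)

    layout = RoomLayout(
        name=str(doc.get("name", "unnamed")),
        width=width,
        height=height,
        color=color,
        east_door=east_door,
        north_door=north_door,
        starts=[tuple(s) for s in doc.get("starts", [])],
        goal_color=doc.get("goal_color"),
    )
    layout.validate()
    return layout


def dump_layout(layout: RoomLayout) -> str:
    """Serialize a layout back to the document format (inverse of load)."""
    lines = [f"name: {layout.name}"]
    if layout.goal_color is not None:
        lines.append(f"goal_color: {layout.goal_color}")
    lines.append("colors:")
    for i in range(layout.height):
        y = layout.height - 1 - i
        row = " ".join(layout.color.get((x, y), VOID) for x in range(layout.width))
        lines.append(f'  - "{row}"')
    lines.append("east_doors:")
    for i in range(layout.height):
        y = layout.height - 1 - i
        row = " ".join("1" if layout.east_door.get((x, y), False) else "0" for x in range(layout.width - 1))
        lines.append(f'  - "{row}"')
    lines.append("north_doors:")
    for i in range(layout.height - 1):
        y = layout.height - 2 - i
        row = " ".join("1" if layout.north_door.get((x, y), False) else "0" for x in range(layout.width))
        lines.append(f'  - "{row}"')
    if layout.starts:
        lines.append("starts:")
        for s in layout.starts:
            lines.append(f"  - [{s[0]}, {s[1]}]")
    return "\n".join(lines) + "\n"


def load_fixture(name: str) -> RoomLayout:
    """Load one of the packaged environments by name (e.g. ``"3x3"``)."""
    path = resources.files("cognav").joinpath("layouts", f"{name}.yaml")
    try:
        text = path.read_text()
    except FileNotFoundError as exc:
        raise LayoutError(f"no packaged layout named {name!r}") from exc
    return load_layout(text)


FIXTURES = (
    "3x3",
    "3x3_alias",
    "4x4",
    "4x4_alias",
    "T_maze",
    "T_maze_alias",
    "Donuts",
    "Tolman",
)


# ---------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------

def step(layout: RoomLayout, pose: WorldPose, action: Action) -> tuple[WorldPose, StepResult]:
    """Execute one action.  Walls absorb; all actions are legal."""
    if not layout.is_room(pose.x, pose.y):
        raise ValueError(f"pose {pose} is not a room")
    action = Action(action)
    if action != Action.STAY and layout.has_door(pose, action):
        new_pose = pose + DELTA[action]
        moved = True
    else:
        new_pose = pose
        moved = False
    result = StepResult(
        observation=layout.color_at(new_pose),
        collisions=layout.collisions_at(new_pose),
        moved=moved,
    )
    return new_pose, result


# ---------------------------------------------------------------------
# World modification: obstacles and kidnapping
# ---------------------------------------------------------------------

def _edge_key(layout: RoomLayout, pose: WorldPose, action: Action) -> tuple[str, tuple[int, int]]:
    """Resolve (pose, direction) to the underlying shared-side entry."""
    action = Action(action)
    if action == Action.STAY:
        raise ValueError("an obstacle edit names a direction, not Stay")
    x, y = pose.x, pose.y
    if action == Action.NORTH:
        key = ("north", (x, y))
    elif action == Action.SOUTH:
        key = ("north", (x, y - 1))
    elif action == Action.EAST:
        key = ("east", (x, y))
    else:
        key = ("east", (x - 1, y))
    kind, (kx, ky) = key
    dx, dy = (1, 0) if kind == "east" else (0, 1)
    if not (layout.is_room(kx, ky) and layout.is_room(kx + dx, ky + dy)):
        raise ValueError(f"{action.name} side of {pose} is not an interior shared side")
    return key


def add_obstacle(layout: RoomLayout, pose: WorldPose, action: Action) -> RoomLayout:
    """Return a copy with the named interior shared side turned into a wall."""
    kind, key = _edge_key(layout, pose, action)
    new = copy.deepcopy(layout)
    (new.east_door if kind == "east" else new.north_door)[key] = False
    new.validate()
    return new


def remove_obstacle(layout: RoomLayout, pose: WorldPose, action: Action) -> RoomLayout:
    """Return a copy with the named interior shared side turned into a door."""
    kind, key = _edge_key(layout, pose, action)
    new = copy.deepcopy(layout)
    (new.east_door if kind == "east" else new.north_door)[key] = True
    new.validate()
    return new


def seal_room(layout: RoomLayout, pose: WorldPose) -> RoomLayout:
    """Close every side of ``pose`` — the Donut "closed room" obstacle."""
    if not layout.is_room(pose.x, pose.y):
        raise ValueError(f"{pose} is not a room")
    new = copy.deepcopy(layout)
    for a in MOVES:
        if new.has_door(pose, a):
            kind, key = _edge_key(new, pose, a)
            (new.east_door if kind == "east" else new.north_door)[key] = False
    new.validate(allow_sealed=True)
    return new


def kidnap(layout: RoomLayout, target: WorldPose) -> WorldPose:
    """Teleport: return the new ground-truth pose, with no signal to the agent."""
    if not layout.is_room(target.x, target.y):
        raise ValueError(f"kidnap target {target} is out of bounds or void")
    return target
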