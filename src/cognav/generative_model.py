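"""The agent's parameter store: Dirichlet counts with growth operations.

The generative model over a maze is parameterized by count tensors whose
normalized slices are categorical distributions:

* ``A_o[o, s]`` — observation (floor color) likelihood ``P(o | s)``.
* ``A_p[p, s]`` — position likelihood ``P(p | s)``; each state is bound
  near-deterministically to one internal pose.
* ``B_s[s', s, a]`` — state transition ``P(s_t | s_{t-1}, a)``.
* ``B_p`` — deterministic position transition: ``(pose, action) → pose``.

Observation, position and state supports all start at size one and only
ever grow; growth pads with the base pseudo-count ``eps`` so that every
previously learned conditional is preserved bit-exactly and new slices
normalize to uniform ("the agent cannot predict which observation to
expect at a newly predicted location").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .actions import Action, DELTA, N_ACTIONS

Pose = tuple[int, int]

#: Pseudo-count assigned to a pose→state binding; normalizing the A_p row
#: of a bound pose then puts essentially all mass on the bound state.
BIND_COUNT = 100.0


def normalize(counts: np.ndarray, axis: int = 0) -> np.ndarray:
    """Dirichlet mean: counts divided by their (axis) sum."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum(axis=axis, keepdims=True)
    return counts / total


@dataclass(frozen=True)
class Preference:
    """Prior preference over observations.

    Induces ``log P(o)`` as a softmax over the observation support with
    logit ``weight`` on the target color and 0 elsewhere; ``weight = 0``
    (or no target) is the uniform, pure-exploration preference.
    """

    target: str | None = None
    weight: float = 0.0

    def log_probs(self, colors: list[str]) -> np.ndarray:
        logits = np.zeros(len(colors))
        if self.target is not None and self.target in colors:
            logits[colors.index(self.target)] = self.weight
        logits -= logits.max()
        return logits - np.log(np.exp(logits).sum())


class DuplicateSupportError(ValueError):
    """Raised when re-adding a color/pose already in the model support."""


class BindingError(ValueError):
    """Raised when a pose is re-bound to a different state."""


@dataclass
class CognitiveModel:
    """Dirichlet-count generative model of a room maze.

    Learning rates: ``eta_exp`` for experienced transitions/observations,
    ``eta_im`` for imagined (predicted) transitions — deliberately weaker
    so that imagined links never outweigh experienced ones — and
    ``eta_neg`` for negative learning when a collision contradicts a
    believed-open passage.
    """

    eps: float = 0.025
    eta_exp: float = 1.0
    eta_im: float = 0.1
    eta_neg: float = 1.0
    #: Ablation switch: when False, collisions never unlearn or suppress
    #: a believed-open passage (used by the re-mapping control).
    negative_learning: bool = True

    colors: list[str] = field(default_factory=list)
    poses: list[Pose] = field(default_factory=list)
    n_states: int = 0

    A_o: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    A_p: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    B_s: np.ndarray = field(default_factory=lambda: np.zeros((0, 0, N_ACTIONS)))
    B_p: dict[tuple[Pose, Action], Pose] = field(default_factory=dict)

    #: Pose-transition edges suppressed by collision evidence.
    blocked: set[tuple[Pose, Action]] = field(default_factory=set)
    #: (state, action) pairs whose imagined link has already been counted.
    _imagined: set[tuple[int, Action]] = field(default_factory=set)
    #: (state, action) pairs confirmed by an experienced crossing.
    _experienced: set[tuple[int, Action]] = field(default_factory=set)
    _pose_state: dict[Pose, int] = field(default_factory=dict)

    # -- construction --------------------------------------------------
    @classmethod
    def initial(cls, origin: Pose = (0, 0), **kw) -> "CognitiveModel":
        """One state bound to the exploration origin, empty color support."""
        m = cls(**kw)
        m.poses = [origin]
        m.n_states = 1
        m.A_o = np.zeros((0, 1))
        m.A_p = np.full((1, 1), m.eps)
        m.B_s = np.full((1, 1, N_ACTIONS), m.eps)
        m.bind_pose_to_state(origin, 0)
        return m

    # -- support queries ----------------------------------------------
    @property
    def n_colors(self) -> int:
        return len(self.colors)

    @property
    def n_poses(self) -> int:
        return len(self.poses)

    def color_index(self, color: str) -> int:
        return self.colors.index(color)

    def pose_index(self, pose: Pose) -> int:
        return self.poses.index(pose)

    def state_of_pose(self, pose: Pose) -> int | None:
        return self._pose_state.get(tuple(pose))

    def pose_of_state(self, state: int) -> Pose | None:
        for pose, s in self._pose_state.items():
            if s == state:
                return pose
        return None

    def dims(self) -> tuple[int, int, int]:
        """(observations, positions, states) — monotone over an episode."""
        return (self.n_colors, self.n_poses, self.n_states)

    # -- normalized views ----------------------------------------------
    def obs_likelihood(self) -> np.ndarray:
        """``P(o | s)``, columns normalized."""
        return normalize(self.A_o, axis=0)

    def state_given_pose(self, pose: Pose) -> np.ndarray:
        """``P(s | p)`` — the A_p row of ``pose``, normalized over states."""
        return normalize(self.A_p[self.pose_index(pose), :], axis=0)

    def transition(self, action: Action) -> np.ndarray:
        """``P(s' | s, a)`` for one action, columns normalized."""
        return normalize(self.B_s[:, :, int(action)], axis=0)

    # -- growth --------------------------------------------------------
    def grow_state(self) -> int:
        """Add a state dimension; returns the new state id.

        The new A_o column is all-eps (normalizes to uniform), the new
        A_p column is all-eps until a pose is bound, and B_s gains an
        all-eps row and column.  Existing counts are untouched.
        """
        n = self.n_states
        self.A_o = np.pad(self.A_o, ((0, 0), (0, 1)), constant_values=self.eps)
        self.A_p = np.pad(self.A_p, ((0, 0), (0, 1)), constant_values=self.eps)
        self.B_s = np.pad(self.B_s, ((0, 1), (0, 1), (0, 0)), constant_values=self.eps)
        self.n_states = n + 1
        return n

    def grow_color(self, color: str) -> int:
        """Extend the observation support with a newly sighted color."""
        if color in self.colors:
            raise DuplicateSupportError(f"color {color!r} already in support")
        self.colors.append(color)
        self.A_o = np.pad(self.A_o, ((0, 1), (0, 0)), constant_values=self.eps)
        return len(self.colors) - 1

    def grow_pose(self, pose: Pose) -> int:
        """Extend the position support with a newly predicted pose."""
        pose = tuple(pose)
        if pose in self.poses:
            raise DuplicateSupportError(f"pose {pose} already in support")
        self.poses.append(pose)
        self.A_p = np.pad(self.A_p, ((0, 1), (0, 0)), constant_values=self.eps)
        return len(self.poses) - 1

    def record_pose_transition(self, pose: Pose, action: Action, new_pose: Pose) -> None:
        """Record the deterministic ``B_p`` increment (pose, action) → pose'."""
        key = (tuple(pose), Action(action))
        existing = self.B_p.get(key)
        new_pose = tuple(new_pose)
        if existing is not None and existing != new_pose:
            raise ValueError(f"B_p already maps {key} to {existing}, not {new_pose}")
        self.B_p[key] = new_pose

    def pose_successor(self, pose: Pose, action: Action) -> Pose | None:
        """Follow B_p; ``None`` for unknown or collision-suppressed edges."""
        action = Action(action)
        if action == Action.STAY:
            return tuple(pose)
        key = (tuple(pose), action)
        if key in self.blocked:
            return None
        return self.B_p.get(key)

    def bind_pose_to_state(self, pose: Pose, state: int) -> None:
        """Tie a pose to a state so ``P(s | p)`` is (near-)one-hot on it."""
        pose = tuple(pose)
        bound = self._pose_state.get(pose)
        if bound is not None and bound != state:
            raise BindingError(f"pose {pose} already bound to state {bound}")
        if state in set(self._pose_state.values()) and bound != state:
            raise BindingError(f"state {state} already bound to another pose")
        self.A_p[self.pose_index(pose), state] = BIND_COUNT
        self._pose_state[pose] = state

    # -- snapshot / graph export --------------------------------------
    def to_snapshot(self) -> dict:
        """JSON-serializable snapshot (dimensions, count tensors, pose table)."""
        return {
            "negative_learning": self.negative_learning,
            "eps": self.eps,
            "eta_exp": self.eta_exp,
            "eta_im": self.eta_im,
            "eta_neg": self.eta_neg,
            "colors": list(self.colors),
            "poses": [list(p) for p in self.poses],
            "n_states": self.n_states,
            "A_o": self.A_o.tolist(),
            "A_p": self.A_p.tolist(),
            "B_s": self.B_s.tolist(),
            "B_p": [[list(k[0]), int(k[1]), list(v)] for k, v in self.B_p.items()],
            "blocked": [[list(k[0]), int(k[1])] for k in sorted(self.blocked)],
            "imagined": [[int(s), int(a)] for s, a in sorted(self._imagined)],
            "experienced": [[int(s), int(a)] for s, a in sorted(self._experienced)],
            "pose_state": [[list(p), int(s)] for p, s in self._pose_state.items()],
        }

    @classmethod
    def from_snapshot(cls, snap: dict) -> "CognitiveModel":
        m = cls(eps=snap["eps"], eta_exp=snap["eta_exp"], eta_im=snap["eta_im"], eta_neg=snap["eta_neg"])
        m.negative_learning = bool(snap.get("negative_learning", True))
        m.colors = list(snap["colors"])
        m.poses = [tuple(p) for p in snap["poses"]]
        m.n_states = int(snap["n_states"])
        m.A_o = np.array(snap["A_o"], dtype=float).reshape(len(m.colors), m.n_states)
        m.A_p = np.array(snap["A_p"], dtype=float).reshape(len(m.poses), m.n_states)
        m.B_s = np.array(snap["B_s"], dtype=float).reshape(m.n_states, m.n_states, N_ACTIONS)
        m.B_p = {(tuple(p), Action(a)): tuple(v) for p, a, v in snap["B_p"]}
        m.blocked = {(tuple(p), Action(a)) for p, a in snap["blocked"]}
        m._imagined = {(int(s), Action(a)) for s, a in snap["imagined"]}
        m._experienced = {(int(s), Action(a)) for s, a in snap.get("experienced", [])}
        m._pose_state = {tuple(p): int(s) for p, s in snap["pose_state"]}
        return m

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_snapshot(), fh)

    @classmethod
    def load(cls, path) -> "CognitiveModel":
        with open(path) as fh:
            return cls.from_snapshot(json.load(fh))

    def to_graph(self, min_prob: float = 0.2) -> nx.DiGraph:
        """Cognitive graph: states as nodes, argmax-credible transitions as edges."""
        g = nx.DiGraph()
        obs = self.obs_likelihood() if self.n_colors else None
        for s in range(self.n_states):
            pose = self.pose_of_state(s)
            color = self.colors[int(np.argmax(obs[:, s]))] if obs is not None else None
            g.add_node(s, pose=str(pose), color=str(color))
        for a in (Action.NORTH, Action.EAST, Action.SOUTH, Action.WEST):
            t = self.transition(a)
            for s in range(self.n_states):
                s2 = int(np.argmax(t[:, s]))
                if s2 != s and t[s2, s] >= min_prob:
                    g.add_edge(s, s2, action=a.name, probability=float(t[s2, s]))
        return g
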