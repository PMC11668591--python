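# cognav — active-inference navigation with a growing cognitive map

`cognav` is a research library for studying spatial learning in
room-structured mazes. Its agent builds a *cognitive map* — a graph of
discrete states tied to internally tracked positions — while navigating,
and differs from observation-driven map learners in one key way: the map
**expands over predictions**. Every door the agent can see from the room it
occupies spawns a state for the un-visited room behind it, so plans can
target places that have never been observed. The result is near-oracle
exploration of mazes whose size and observation alphabet the agent does not
know in advance, robust re-localization after being moved without warning
("kidnapping"), and rapid re-mapping when a learned passage is suddenly
blocked — the classic Tolman detour behavior.

It is aimed at computational-neuroscience and robotics researchers who want
a compact, fully inspectable discrete model of map learning, localization
under aliased observations, and exploration/exploitation arbitration.

## The model

The agent maintains Dirichlet counts for a POMDP generative model over
states `s`, internal positions `p`, floor-color observations `o`, and
actions `a` (N/E/S/W/Stay):

* observation likelihood `A_o = P(o | s)`;
* position likelihood `A_p = P(p | s)`, near-one-hot per state;
* state transitions `B_s = P(s_t | s_{t-1}, a)`;
* a deterministic position map `B_p : (p, a) → p'` grown as positions are
  discovered.

Perception minimizes variational free energy: the per-step posterior over
states combines the transition prior, the observation likelihood, the
position factor, and the proprioceptive move/bump outcome. When the
observation is too surprising under the dead-reckoned state (e.g., after a
kidnap), the position factor is suspended and the agent re-localizes from
observations alone before learning resumes.

Action selection minimizes expected free energy. Each candidate policy
`π` (a shortest believed route to a target state, or a single crossing of
an unconfirmed door) is scored by

```
G(π) = Σ_τ [ −(state info gain) − (parameter info gain) − E[log P(o_τ)] + (collision risk) ]
```

and a policy is sampled from `σ(−γ·G)`. The parameter-information term —
the expected Dirichlet-count change of `A_o` and `B_s` — is what drives
exploration: imagined states with uniform observation columns and
unconfirmed transitions are worth an order of magnitude more than anything
already learned. With a preferred observation (utility weight `w > 0`) the
same objective produces goal-directed navigation. Collisions that
contradict a believed-open passage trigger negative parameter learning,
which re-routes the transition mass to a self-transition and lets the agent
re-plan around the blockage.

Details, defaults and numerical choices are documented in
[docs/methods.md](docs/methods.md).

## A worked example

```bash
python examples/explore_maze.py
```

```
outcome:           learned
steps to learn:    14
oracle (min steps to visit all rooms): 11
final model size:  9 states, 9 colors, 9 positions
```

Starting from a single internal state, the agent learned the full 3x3 maze
(9 states, one per room) in 14 steps. The oracle line is the exact minimum
number of moves needed just to *visit* all nine rooms from that start; the
agent needs a few more because exploration only ends when every door has
been crossed at least once — the believed transition structure must match
the ground truth with at least 60% confidence on every door.

The other example scripts each demonstrate one capability and print the
numbers discussed above: `goal_navigation.py` (kidnap + goal seeking;
steps vs. the shortest-path oracle), `tolman_detours.py` (route-choice
counts under movable blockages), `donut_remapping.py` (re-planning verdict
with and without negative learning), and `oracle_bounds.py` (exact lower
bounds for all packaged mazes).

A thin CLI exposes the experiment suites:

```bash
cognav oracle                      # checksums for all packaged layouts
cognav explore --env 4x4 --runs 20 --seed 1 --out out/
cognav tolman --agents 10 --runs 12 --seed 3 --out out/
cognav donut --seed 0 --ablate-negative
```

## Layout format

Mazes are small YAML documents: a color grid (one token per room, `.` for
void cells), two gate grids for the horizontal and vertical shared sides
(`1`/`door`, `0`/`wall`), designated start poses and an optional goal
color. `cognav.room_world` provides the reader, writer, and the packaged
reconstructions of the eight study environments plus obstacle editing
(shared-side blocks, sealed rooms, kidnapping).
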