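# Methods

`cognav` implements a discrete active-inference agent that learns a
*dynamically expanding* cognitive map of a room-structured maze while
navigating it. This note records the model, the numerical choices that make
it work, and what the packaged experiments do and do not demonstrate.

## The world

A maze is a rectangular grid of rooms; non-rectangular shapes (T, donut,
Tolman) use void cells that are not rooms. Each room emits a single floor
color (the only visual observation) and exposes, for the room the agent
occupies, a per-side collision flag (door or wall) — the output one would
expect from a lower perceptual layer summarizing vision and border-cell-like
obstacle detection. Actions are the four cardinal moves plus Stay; moving
into a wall leaves the pose unchanged. Obstacles can be added on shared
sides, a room can be sealed entirely, and the agent can be silently
teleported ("kidnapped"); none of these signal the agent.

The eight packaged layouts range from 8 to 23 rooms. Their door placements
were reconstructed so that the exact coverage oracle (below) reproduces the
reference lower bounds: 11 (3x3), 15 (4x4), 9 (T maze, averaged over its
three arm-end starts), 9.5 (aliased T maze, averaged over the arm ends plus
the junction), 13 (Donut). Aliased variants repeat floor colors across
rooms; the aliased T maze places the stem-bottom color in three rooms so a
single observation cannot localize the agent.

## Generative model

The agent's parameters are Dirichlet count tensors whose normalized slices
are categorical distributions:

* `A_o[o, s]` — observation likelihood `P(o | s)`;
* `A_p[p, s]` — position likelihood; each state is bound near-determin-
  istically to one internal pose (binding count 100 against a base
  pseudo-count ε per cell), so `P(s | p)` is one-hot up to smoothing;
* `B_s[s', s, a]` — state transitions per action;
* `B_p` — a *deterministic* position-transition map `(pose, action) → pose`,
  grown as positions are discovered, with collision-suppressed edges kept in
  a separate set.

Internal poses are integer offsets from the exploration origin `(0,0)`,
updated by dead reckoning only when proprioception reports a room change.
Observation, position and state supports all start at size one and only
grow; growth pads with ε so existing counts are preserved bit-exactly and
new slices normalize to uniform.

Defaults: ε = 0.025, experienced learning rate η_exp = 1.0, imagined rate
η_im = 0.1 (reverse imagined links at η_im/2), negative rate η_neg = 1.0.
The ε/η ratios are chosen so that, at the sizes of these mazes (8–23
states), a transition supported only by imagination stays *below* the 60%
map-completeness bar while a single experienced crossing passes it: with a
larger ε the tail mass across ~20 states would keep even experienced
transitions below 60%, and with a larger η_im imagination alone would pass,
ending exploration before any door had been tested. Imagined increments are
applied once per (state, direction) — re-imagining is idempotent — so
imagination can never outweigh experience through repetition.

## Inference

Per-step filtering over states: the posterior is proportional to
(transition prior) × (observation likelihood) × (position factor), where the
prior pushes the previous posterior through `B_s` for the executed action
when the agent moved and carries over unchanged when it did not. Two
additional likelihood factors matter in practice:

* **Move/bump consistency.** Proprioception reports whether the move
  succeeded. A state whose bound pose has a believed-open side in the
  attempted direction is inconsistent with a bump (likelihood 0.1), and one
  with a remembered wall is inconsistent with a successful move; unknown
  sides are neutral. Without this factor a lost agent that bumps a wall
  gains no evidence and can repeat the same failed move indefinitely.
* **Surprise detection.** A silent relocation cannot be read off the
  normalized posterior (the position factor keeps it confidently wrong).
  The trigger is the surprise of the observation under the dead-reckoned
  state — the state bound to the advanced pose estimate. An un-visited
  state has a uniform observation column, so its surprise is exactly
  `log n_colors`; the threshold `log n_colors + 1` is therefore never
  tripped by honest frontier visits, while a learned state showing the
  wrong color trips it at once. Colors that were only just added to the
  support are exempt (maximally surprising, yet contradicting nothing).

When surprised (or when the posterior max falls below the certainty
threshold 0.5), the agent drops the position factor, re-infers from the
observation alone, and enters **lost mode**: the pose estimate freezes and
all model writes pause. The lost-mode re-estimation weights states by their
`A_o` column mass — an empirical visitation prior. Without it the many
never-observed states, each compatible with any observation, soak up most
of the posterior and a young map could never recover. Recovery requires
confidence ≥ 0.7 (hysteresis against mode flapping) and re-anchors the pose
to the most probable state's bound pose. A step that passed through lost
mode never contributes transition learning, even if confidence recovered
within the same step.

All model writes additionally require confidence ≥ 0.7: updating at
middling confidence writes transitions into half-wrong states, and such
corruption compounds (the agent then plans from a map containing a
displaced copy of part of the maze).

## Structure learning

From every confidently-occupied room the agent expands over *predictions*:
for each open side the predicted pose is added to the position support if
new, a fresh state with a uniform observation column is created and bound
to it if none exists, and weak imagined transition counts connect the
current state to it (with a weaker reverse prior so plans can route through
imagined states without asserting the return door). Blocked sides add a
weak self-transition and suppress the pose edge. This is the property that
makes exploration efficient: un-visited rooms exist in the model *before*
they are observed, so plans can target them from anywhere.

Experienced transitions are reinforced at η_exp in both directions
(experience confirms bi-directionality) and the observed color is credited
to the current state. A collision where the model believed a passage open
triggers **negative learning**: the transition count toward the believed
neighbor drops by η_neg (floored at ε), the removed mass re-routes to the
self-transition, and the pose edge is suppressed. The suppression is
plastic: an open side observed later clears the collision memory, and
re-crossings rebuild the positive belief. Failed moves also teach an
experienced self-transition; both mechanisms count as collision-driven
learning and are disabled together by the ablation switch used in the
re-mapping control.

Exploration is complete when the believed transition probability of every
true door transition is at least 0.6 (checked through a test-harness-only
correspondence that maps internal poses to rooms via the start offset; the
agent never sees it).

## Planning

Candidate policies are (i) the shortest believed action sequence to each
reachable state within the horizon (following `B_p` minus suppressed
edges), (ii) one policy per believed-but-unconfirmed door — walk there and
cross it once — and (iii) Stay. There is no exponential tree search; a
14-step horizon costs the same BFS as a 5-step one.

Each policy is padded with Stay to the horizon (totals comparable across
path lengths) and scored per predicted step by

* **state information gain** — the mutual information between predicted
  state and predicted observation (expected KL from prior to posterior
  belief), non-negative by construction;
* **parameter information gain** — the Dirichlet-update KL of the `A_o` and
  `B_s` counts the step would touch. Three numerical choices here were
  made after observing concrete planner pathologies, and are deliberate:
  the belief is rolled forward under *maximum-likelihood dynamics* (argmax
  successor per state), because with raw count-mean transitions the belief
  diffuses a little every step and, over 10–14 steps, phantom mass on
  far-away states swamps the epistemic terms; the update KL is evaluated at
  the *most credible outcome* (argmax color / successor), because averaging
  over the full predictive is dominated by the enormous but improbable
  updates of near-empty tail cells and makes everything look equally novel;
  and all terms carry a per-step discount of 0.85, because without a time
  preference a novel door one step away scores the same total as one eight
  steps away and the agent churns between distant targets. One experienced
  crossing shrinks a transition's update KL by over an order of magnitude,
  which is what stops the agent re-confirming known doors.
* **utility** — expected log preference of the predicted observation.
  Preferences are a softmax over the color support with logit `w` on the
  target (`w = 0`: uniform, pure exploration; the goal experiments use
  `w = 2`);
* **collision risk** — probability mass spent stepping into a side with
  recorded collision evidence (weight 2).

A policy is sampled from `softmax(−γ·G)` with temperature γ = 8 by default
(γ = 4 in the Tolman protocol, where route alternation is part of the
studied behavior); only its first action is executed and the agent re-plans
every step, which is what lets it re-map on the spot when the world changes.

## Experiments and what they show

* **Exploration** (20 seeded runs per maze, spawning on the designated
  starts): steps until the 60% map-completeness bar. Every run is bounded
  below by the exact coverage oracle — a search over (room, visited-set)
  states, exact for these maze sizes, which a heuristic would not guarantee.
  The agent's first-discovery times track the oracle closely; steps-to-learn
  exceed coverage because every door must also be crossed once.
* **Goal seeking**: after exploration the agent is relocated to a random
  room and must *choose to Stay* at the goal color (stumbling into it does
  not count). With distinct colors the mean excess over the shortest-path
  oracle is ≈ 0; in the aliased T maze a few localization steps remain.
* **Tolman detours**: 10 agents × 3 series × 12 runs, kidnapped to the
  start every 20 steps, utility weight 2, horizon 14. With the blockage at
  A, route-1 completions are structurally impossible and the agents shift
  to route 2; at B (shared by routes 1 and 2) they shift to route 3. Route
  classification uses the last route-distinguishing room visited before
  the goal. This implementation is more exploitative than the reference
  behavior: route 1 takes nearly all free-maze completions rather than
  about half, because at these EFE magnitudes the utility term dominates
  the residual epistemic value of the alternative corridors.
* **Donut re-mapping**: learn, kidnap to a corner, seal the short-path
  room mid-run. The verdict requires reaching the goal the long way with
  at most 4 collisions against the sealed room; disabling collision-driven
  learning makes the agent bump indefinitely (control).

## Known limitations

* The synthetic mazes are deterministic, fully discrete and noise-free;
  passing these tests says nothing about continuous motion, perceptual
  noise, or observation models richer than one color per room.
* Pose tracking is exact dead reckoning. Consequently color aliasing does
  not slow exploration at all here — its cost appears only after
  relocations, when the position factor is suspended. Reference behavior
  in which aliasing slows exploration itself implies a softer position
  model than the deterministic `B_p` used here.
* States are keyed by internal pose, so duplicate states for the same
  physical room cannot arise while tracking is intact — and loop closure
  beyond pose identity (merging states discovered to be identical) is not
  implemented.
* The lost-mode empirical prior assumes relocations land in charted
  territory; being kidnapped into an unexplored region leaves the agent
  lost until it wanders back into known rooms.
* Policy construction assumes the believed `B_p` graph is reliable enough
  for shortest paths; with heavily corrupted maps (prevented in practice by
  the confidence gate) planning degrades silently.
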