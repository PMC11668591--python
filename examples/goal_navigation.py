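"""Goal-directed navigation after a silent relocation.

The agent first learns the Donut maze, is then teleported to a far
corner without being told, and must reach the pink room.  Its first
observation contradicts its dead-reckoned position, so it drops into
"lost" mode, re-localizes from the floor color alone, and then walks
the shortest believed path to the goal, choosing to Stay there.
"""

from cognav import WorldPose, load_fixture, run_episode, shortest_path_steps
from cognav.generative_model import Preference

layout = load_fixture("Donuts")
home = WorldPose(0, 0)
explored = run_episode(layout, home, "explore", seed=11, max_steps=300)
print(f"explored the maze in {explored.steps} steps")

kidnap_to = WorldPose(4, 0)
goal = run_episode(
    layout,
    kidnap_to,
    "goal",
    pref=Preference(target="pink", weight=2.0),
    seed=11,
    max_steps=60,
    agent=explored.agent,
    map_origin=home,
)
oracle = shortest_path_steps(layout, kidnap_to, "pink")
print(f"goal outcome: {goal.outcome} in {goal.steps} steps (oracle: {oracle})")
# With a learned map, the step count matches the shortest-path oracle up
# to the one or two observations needed to re-localize after the kidnap.
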