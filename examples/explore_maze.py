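"""Pure exploration: learn the layout of a 3x3 room maze from scratch.

The agent starts with a single internal state and no knowledge of the
maze's size or colors.  It expands its cognitive map over the predicted
rooms behind every door it sees, and the episode ends when its believed
transition structure matches the ground truth with at least 60%
confidence on every door.
"""

from cognav import AgentConfig, WorldPose, load_fixture, min_coverage_steps, run_episode

layout = load_fixture("3x3")
start = WorldPose(0, 0)
result = run_episode(layout, start, "explore", config=AgentConfig(), seed=7, max_steps=200)

oracle = min_coverage_steps(layout, start)
model = result.agent.model
print(f"outcome:           {result.outcome}")
print(f"steps to learn:    {result.steps}")
print(f"oracle (min steps to visit all rooms): {oracle}")
print(f"final model size:  {model.n_states} states, {model.n_colors} colors, {model.n_poses} positions")
# The agent needs a few more steps than the oracle: the oracle only has
# to *visit* every room, while the agent must also cross every door at
# least once to be confident about the transition structure.
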