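"""Re-mapping when a learned path is suddenly blocked.

After learning the Donut maze the agent is kidnapped to a corner and
sent toward the pink room; two steps into the journey the room on its
planned short path is sealed off.  Standing next to the sealed room the
agent perceives the collision, unlearns the believed-open passage
(negative parameter learning), re-plans, and reaches the goal the long
way around.  The control run disables negative learning: the agent
keeps believing the passage open and never gets there.
"""

from cognav.experiments import run_donut_remapping

ok = run_donut_remapping(seed=3)
print(
    f"negative learning on : verdict={ok.verdict}  goal={ok.goal_reached} "
    f"steps={ok.steps}  bumps={ok.bumps}  negative updates={ok.negative_events}"
)
ablated = run_donut_remapping(seed=3, negative_learning=False)
print(
    f"negative learning off: verdict={ablated.verdict}  goal={ablated.goal_reached} "
    f"steps={ablated.steps}  bumps={ablated.bumps}"
)
# The verdict requires reaching the goal with at most a handful of
# collisions against the sealed room; the ablated agent bumps forever.
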