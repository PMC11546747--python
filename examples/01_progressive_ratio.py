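"""Simulate a progressive-ratio (PR) session and read out the breakpoint.

The PR schedule escalates the lever-press requirement each trial
(1, 2, 4, 6, 9, ... 118, ...); the session ends at the first 10-minute
window without a reward.  The breakpoint — the last requirement completed —
indexes how hard the agent is willing to work for the reward.
"""

from rewardseek import AgentParams, ScheduleSpec, pr_requirement_sequence, simulate_pr_session

print("First 16 PR requirements:", pr_requirement_sequence(16))

schedule = ScheduleSpec.for_task("food_PR")
agent = AgentParams(press_rate=0.8)  # presses/s while a trial is live
events = simulate_pr_session(agent, schedule, seed=1)

rewards = events.times_of("reward")
breakpoint_ratio = pr_requirement_sequence(len(rewards))[-1]
print(f"Rewards earned: {len(rewards)}")
print(f"Breakpoint (last ratio completed): {breakpoint_ratio} presses")
print(f"Session ended at {events.duration:.0f} s")
# The breakpoint rises with press_rate: a more motivated agent sustains
# pressing through larger requirements before the 10-min timeout fires.
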