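"""Simulate a cow-like GPS bout and summarize its per-state kinematics.

The generator switches between resting, grazing and walking with bouts of
a few minutes, draws Weibull step lengths and wrapped Cauchy turning
angles per state, and adds 1 m GPS noise.  The summary shows mean speed
[m/s] and mean absolute turning angle [rad] per state; walking should be
fast and straight, resting slow and tortuous (noise inflates the slow
states' speeds toward the noise floor, as in the real device test).
"""

from grazetrack import SimConfig, behavioral_budget, simulate_track, summarize_state_kinematics

sim = simulate_track(SimConfig(n_positions=3000, seed=42))
budget = behavioral_budget(sim.track.labels)
print("state budget:", {s: round(p, 3) for s, p in budget.proportions.items()})
print(summarize_state_kinematics(sim.track).round(3))
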