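"""Closed-loop decoding: a virtual user runs the pick-and-place protocol.

A simulated participant reaches from the rest basket to the four targets
(power / tripod / point grasps and hand-open) over 8 protocol blocks.  The
MAV trajectories go through the real dwell selector and grasp state
machine, so every printed motor command was gated exactly as on the device:
closing grasps only from an open, re-armed hand; opening only from a closed
hand.
"""

import numpy as np

from abstractmyo import BlockPlan, VirtualUserProfile, simulate_session

profile = VirtualUserProfile()  # 5 deg aim scatter, 15% mis-aim rate
bucket, truth = simulate_session(profile, BlockPlan.default(8), rng=11)

print(f"blocks: 8   planned grasps: {truth.n_planned_grasps}")
print(f"motor commands: {len(bucket.commands)} "
      f"(closing {sum(1 for c in bucket.commands if c.target != 4)}, "
      f"open {sum(1 for c in bucket.commands if c.target == 4)})")
print(f"unexpected grasps -> feedback events: {len(bucket.feedback)}")
print(f"extra reaches (retries after mis-aims/misses): {truth.n_extra_reaches}")

print("\nfirst six commands (timestamp, target, grasp, decision angle):")
for cmd in bucket.commands[:6]:
    print(f"  {cmd}")

wrong = [i for i, (c, it) in enumerate(zip(bucket.commands, truth.intended_targets))
         if c.target != it]
print(f"\ncommands that missed the user's intent: {wrong}")
print("Each of these triggered a feedback event a few seconds later; that "
      "pairing is what the adaptation stage learns from.")
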