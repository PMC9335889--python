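"""Boundary adaptation: learn customized decision boundaries from a session.

A virtual user who systematically aims high on target 1 — drifting toward
the 1–2 boundary, so some power-grasp attempts execute as tripod — plays a
full 16-block session.  Feedback events are labeled back to their motor
commands; the correct commands train per-target Gaussian angle models; the
equal-density crossings of adjacent models give the customized boundaries;
and the unexpected commands verify how many wrong grasps the new
boundaries would have routed to the intended target ("corrections").
"""

from abstractmyo import (
    BlockPlan,
    VirtualUserProfile,
    adaptation_report,
    render_markdown,
    simulate_session,
)

# aims ~6 deg high on target 1 and ~2 deg high on target 2
profile = VirtualUserProfile(aim_mean=(17.0, 36.0, 56.25, 78.75), misaim_prob=0.05)
bucket, _ = simulate_session(profile, BlockPlan.default(16), rng=3)

report = adaptation_report(bucket, user="biased-sim")
print(render_markdown(report))

b_def = report["boundaries"]["default"]
b_new = report["boundaries"]["customized"]
print(f"boundary 1-2 moved {b_new[0] - b_def[0]:+.1f} deg, tracking the high aim "
      "on target 1; the verification row counts how many of the "
      f"{report['counts']['n_feedback']} unexpected grasps the customized "
      f"boundaries correct ({report['counts']['n_corrected']}).")
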