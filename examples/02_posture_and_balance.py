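"""Check postures with alignment rules and estimate lateral lean.

Each rule compares one coordinate of two joints; the posture is correct
when every included rule's difference is inside its error range. Lean is
the shoulder-height difference normalized by shoulder width: a
dimensionless value whose sign names the lower shoulder.
"""

import math

import steadywalk as sw

template = sw.upright_template()
config = sw.ThresholdConfig()

# An ideal stance passes every rule.
ideal = sw.standing_frames(sw.WalkerParams(noise_sd=0.0, seed=0), 0.1).frames[0]
verdict = sw.evaluate_posture(ideal, template, config)
print(f"ideal stance correct: {verdict.correct}")

# A subject leaning 8 degrees to the right fails the shoulders-level rule.
leaning = sw.standing_frames(
    sw.WalkerParams(lean_deg=8.0, noise_sd=0.0, seed=0), 0.1
).frames[0]
verdict = sw.evaluate_posture(leaning, template, config)
print(f"8-degree lean correct: {verdict.correct}, misaligned: "
      f"{sorted(j.value for j in verdict.misaligned_joints)}")

level = sw.balance_level(leaning, config)
print(f"balance value {level.value:+.3f} (= sin 8 deg = "
      f"{math.sin(math.radians(8)):+.3f}), side={level.side}, "
      f"alert={level.alert}")

# A patient who cannot move one arm: exclude arm rules instead of failing
# them — the body-part mask is the therapist's tool for exactly this.
no_arms = sw.ThresholdConfig(included_parts={"shoulders", "trunk", "legs"})
lifted = sw.SkeletonFrame(t=0.0, joints=dict(ideal.joints))
hand = lifted.joints[sw.JointName.HandLeft]
lifted.joints[sw.JointName.HandLeft] = sw.Joint(
    sw.JointName.HandLeft, hand.x, hand.y + 0.5, hand.z
)
print(f"lifted hand, arms checked:  "
      f"{sw.evaluate_posture(lifted, template, config).correct}")
print(f"lifted hand, arms excluded: "
      f"{sw.evaluate_posture(lifted, template, no_arms).correct}")
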