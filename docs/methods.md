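# Methods

## Posture model

A posture is a conjunction of pairwise alignment constraints. Each rule
compares one coordinate (x or y) of two joints and passes when the signed
difference lies within ±ε, boundary inclusive. Restricting rules to the
lateral and vertical axes keeps the checks in the frontal plane, where
balance faults live; a forward-slump check (z-axis, ShoulderCenter vs
HipCenter) is deliberately not in the default template but can be added as
a custom rule.

The default `upright` template encodes the standing stance — level
shoulders and hips, trunk vertical, hands at the sides and not lifted,
feet under the shoulders — one rule per clause:

| rule | joints | axis | ε (m) | part |
|---|---|---|---|---|
| shoulders_level | ShoulderLeft / ShoulderRight | y | 0.04 | shoulders |
| back_straight | ShoulderCenter / HipCenter | x | 0.04 | trunk |
| hips_level | HipLeft / HipRight | y | 0.04 | trunk |
| hand_{l,r}_at_side | Hand / same-side Hip | x | 0.12 | arms |
| hand_{l,r}_not_lifted | Hand / same-side Hip | y | 0.15 | arms |
| foot_{l,r}_under_shoulder | Ankle / same-side Shoulder | x | 0.10 | legs |

The ε defaults are sized to adult anthropometry (so that an ideal stance
passes across the 1.5–1.9 m height range) and are meant to be tuned: the
`ThresholdConfig.strictness` multiplier scales all of them at once, and
per-rule overrides are absolute (an override beats strictness, because a
therapist-set value should not silently drift when global strictness
changes). Error ranges are plain meters; a normalization hook (override
per rule) covers cases where a clinic prefers subject-relative units.

During the walk (step 2) only the zero-ideal-difference rules apply —
shoulders_level, back_straight, hips_level — since arm swing and stride
make the arm and foot rules meaningless mid-gait.

## Balance estimate

balance = (ShoulderLeft.y − ShoulderRight.y) / |ShoulderLeft.x −
ShoulderRight.x|, clamped to [−1, 1]. Normalizing by the lateral shoulder
distance makes the value dimensionless and comparable across subjects.
The alert threshold `balance_epsilon` defaults to 0.1 (≈ 5.7° of lean);
a shoulder-width below 1 mm is treated as a data error rather than
produce an unbounded ratio.

## Exercise state machine

`step` ∈ {1, 2, 3} and never decreases within an attempt.

* **Step 1.** Compliance = pelvis within `start_zone_tolerance` (0.15 m)
  of the start line AND the full upright template passing. The hold timer
  accumulates only over consecutive compliant frames and resets to zero on
  any non-compliant frame (the stance must be held without swinging);
  after `hold_seconds` (default 3 s) the walk begins.
* **Step 2.** Per frame: the balance estimate, the walking rule subset,
  and the corridor check (both ankles and the pelvis against
  corridor_center ± corridor_half_width, default half-width 0.25 m,
  boundary inclusive — on the line is not a touch). Progress is the
  clamped fraction of pelvis z-advance over the course. The finish is
  detected from pelvis z-advance ≥ course_length; the pelvis is the most
  stable proxy for body position, and the start-zone tolerance absorbs
  the choice. The backward variant negates the z mapping and is exposed
  as `direction="backward"` but is not exercised by the test-suite.
* **Step 3.** Same hold logic at the finish line; on completion the
  attempt terminates with a congratulation (no errors) or a conclusion
  listing one corrective message per distinct fault, ordered by first
  occurrence.

Faults (`balance`, `posture`, `margin`) are debounced with
`debounce_frames` = 5 (≈ 0.17 s at 30 fps): shorter blips are treated as
sensor flicker, and one maximal violating run is one countable error —
matching how a therapist counts mistakes, not frames. Balance and margin
events are *intrusive* (they carry fall risk); instructions and
misaligned-joint hints are informational. Attempt duration is stored in
results and reports only, never in event payloads, so a renderer cannot
accidentally show the patient a stopwatch.

## Synthetic walker

The generator emulates a sensor capture of one attempt: a standing hold
(hold_seconds + 1 s, the margin letting the monitor confirm the hold), a
constant-speed walk over the course, and a finish hold. Defaults — 1.7 m
subject, 0.5 m/s walking speed, 30 fps, 3 mm Gaussian joint noise, 1 cm
lateral sway at 0.3 Hz, 3 cm arm swing — are chosen as a plausible slow
rehabilitation gait captured by a consumer depth sensor.

Joint placement comes from a fixed anthropometric table
(`data/anthropometry.json`) of per-joint offsets as fractions of height,
left/right symmetric, loosely following classical body-segment proportion
tables (shoulder height 0.818H, hip 0.53H, shoulder half-width 0.1295H).
The hand height (0.46H) keeps the ideal hands-by-the-sides differences
inside the default ε across 1.5–1.9 m subjects.

Lean is a vertical shear of the upper body about the hip center: each
joint above the pelvis drops by (x − x_hip)·sin(lean). A shear rather
than a rigid rotation is a deliberate modelling choice: it leaves the
lateral shoulder distance unchanged, so the normalized balance estimate
recovers exactly sin(lean) from noiseless frames and the
generator/detector agreement can be asserted to 1e-9 — a rigid rotation
would recover tan(lean) and blur the sharp-threshold tests. At clinical
lean angles (< 12°) the two differ by under 2% of the value. Drift and
sway are rigid lateral translations (invisible to posture rules by
translation invariance, visible to the corridor check); arm swing is an
antiphase longitudinal offset of the arm joints, invisible to the x/y
rules. Noise is drawn from one seeded generator per stream in fixed joint
order, making streams bitwise reproducible after canonical serialization.

`inject_fault` overlays a labeled impairment (lean step-change, rigid
lateral drift, or a freeze that pins joints to the window-start pose) on
an existing stream and returns the ground-truth window for assertions.

What the walker does *not* emulate: true gait dynamics (no stance/swing
phases, no vertical pelvis oscillation, no ground-contact kinematics),
occlusion and tracking dropouts, or the heavy-tailed noise of real depth
sensors. Passing tests therefore demonstrate the correctness of the
monitoring logic against its geometric definitions, not detector
performance on real patient recordings.

## Serialization and reports

Streams are line-delimited JSON (one metadata header, one object per
frame) with strictly increasing timestamps; incomplete frames are
rejected at parse time with the line number rather than imputed. Schema
files for every JSON dialect live in `src/steadywalk/schemas/`. Session
reports store per-attempt results plus totals; parsing recomputes the
totals from the attempt list and rejects mismatches, so a tampered or
truncated report cannot slip through. Therapist updates change only the
fields they name, are validated against the config invariants before
anything is written, and produce a timestamped change-log entry
(timestamps injectable for deterministic tests).

## Numerical and testing choices

Boundary conventions are inclusive everywhere (|d| = ε passes; a joint on
the corridor line is inside). Floating-point knife edges are avoided in
tests by using binary-exact values where exact equality is asserted. The
property suites run on 300–1000 random frames against brute-force
recomputation; the noisy lean-recovery check uses ≥ 300 frames at a fixed
seed and a 3-standard-error band. Problem sizes throughout (540-frame
attempts, 0.3–12 s fixtures) keep the full suite under ~10 s on one core
while still covering every phase transition of the state machine.
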