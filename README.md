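# steadywalk

A sensor-independent monitoring engine for at-home balance-rehabilitation
exercises. Patients with balance disorders (after stroke, traumatic brain
injury, or with neurodegenerative disease) train by walking a short
straight course while keeping an upright posture; a motion sensor tracks
their skeleton, and software must decide — frame by frame, without a
therapist in the room — whether the posture is correct, which side the
patient is tipping toward, and whether they are staying between the
walking lines. `steadywalk` implements that decision engine plus the
surrounding plumbing: a skeleton stream format, the three-step exercise
state machine, feedback events, therapist-facing session reports, and a
seeded synthetic walker so the whole pipeline runs and tests without any
hardware.

It is a library first (Python API + `examples/`), with a thin `steadywalk`
command-line tool for the shell workflows (simulate / run / update /
report). Intended users are rehabilitation-technology developers and
movement-analysis researchers who need a testable, parameterized posture
monitor rather than a GUI.

## The model

A skeleton frame is 20 named joints (Kinect-v1 taxonomy), each a position
(x, y, z) in meters: x lateral, y vertical, z along the walking direction.
Posture is encoded as **alignment rules**: for a rule (a, b, axis, ε) on
frame F,

&nbsp;&nbsp;&nbsp;&nbsp;d = F[a].axis − F[b].axis, &nbsp; pass ⇔ |d| ≤ ε

with ε the rule's *error range* in meters (boundary inclusive). Because
only coordinate differences enter, verdicts are invariant to where the
subject stands and — for rules whose ideal difference is zero — to the
subject's height, so no per-patient calibration is needed. A
`ThresholdConfig` scales all error ranges by a *strictness* factor,
overrides individual rules, and masks whole body parts (arms, legs, trunk,
shoulders) in or out.

Lateral lean is estimated from shoulder asymmetry:

&nbsp;&nbsp;&nbsp;&nbsp;balance = (y_L − y_R) / |x_L − x_R| ∈ [−1, 1]

for the left/right shoulder joints; the sign names the lower shoulder, and
|balance| > balance_epsilon raises the alert (the "red scale" a UI would
show).

The exercise itself is a three-step state machine driven by a `step`
variable: **1** hold the upright posture at the start line for
`hold_seconds`; **2** walk the `course_length` (default 5 m) corridor while
the monitor checks balance, walking posture and the corridor margins;
**3** stop and hold at the finish. Faults are debounced — a violation must
persist `debounce_frames` consecutive frames, and one maximal violating
run counts as exactly one error. Attempt duration is recorded for the
therapist but never placed in patient-facing feedback.

## Worked example

```
$ python examples/03_monitor_attempt.py
clean attempt: success=True, duration=17.0 s, errors=0
events: ['task_instruction', 'task_instruction', 'task_instruction', 'congratulation']

drifting attempt: success=False
  fault 'margin' from t=5.97 to t=14.00 s
  conclusion: Stay between the walking lines.
```

The clean walker holds 3 s at the start, walks 5 m at 0.5 m/s, holds 3 s
at the finish: three task instructions (one per step) and a congratulation,
17.0 s door to door. The second walker drifts laterally 0.1 m per meter
walked; its right ankle crosses the right walking line at t ≈ 6 s and
stays outside until the finish — one continuous margin fault, reported as
a single error with the corrective conclusion a patient would see after
the attempt.

`examples/` contains one short script per capability: stream simulation
and serialization, posture/balance checks, attempt monitoring, fault
injection with ground truth, and session reporting with therapist updates.

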