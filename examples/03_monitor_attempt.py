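"""Run the three-step exercise monitor over simulated attempts.

Step 1: hold an upright posture at the start line. Step 2: walk the 5 m
course. Step 3: stop and hold at the finish. A clean walk succeeds; a
drifting walker touches the corridor margin and collects an error.
"""

import steadywalk as sw

spec = sw.ExerciseSpec()
template = sw.upright_template()
config = sw.ThresholdConfig()

clean = sw.walking_stream(sw.WalkerParams(noise_sd=0.0, seed=1), spec)
result, events = sw.run_attempt(clean, spec, template, config)
print(f"clean attempt: success={result.success}, "
      f"duration={result.duration:.1f} s, errors={len(result.error_events)}")
print("events:", [e.kind for e in events])

drifting = sw.walking_stream(
    sw.WalkerParams(noise_sd=0.0, drift_rate=0.1, seed=1), spec
)
result, events = sw.run_attempt(drifting, spec, template, config)
print(f"\ndrifting attempt: success={result.success}")
for err in result.error_events:
    print(f"  fault '{err.fault_id}' from t={err.start_t:.2f} to "
          f"t={err.end_t:.2f} s")
for msg in result.conclusions:
    print(f"  conclusion: {msg}")
# The drift pushes the subject over the right walking line mid-course; the
# whole excursion counts as ONE margin error, whatever its length.
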