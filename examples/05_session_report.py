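"""Aggregate attempts into a therapist report and adapt the parameters.

The report carries successes, per-fault error counts and durations (the
duration is therapist-only data, never shown to the patient). The
therapist closes the loop with a parameter update — here, loosening the
error ranges and widening the lean threshold for a patient who keeps
tipping sideways mid-walk.
"""

import steadywalk as sw

spec = sw.ExerciseSpec()
template = sw.upright_template()
config = sw.ThresholdConfig()

# Four attempts; in the 2nd and 4th the subject leans 7 degrees to the
# right for a stretch of the walk phase.
attempts = []
for i in range(1, 5):
    stream = sw.walking_stream(sw.WalkerParams(noise_sd=0.0, seed=i), spec)
    if i % 2 == 0:
        stream, _ = sw.inject_fault(stream, "lean", (6.0, 10.0), 7.0)
    result, _ = sw.run_attempt(stream, spec, template, config, index=i)
    attempts.append(result)

report = sw.summarize(attempts, config, session_id="demo", patient_id="p-007")
print(f"attempts={report.totals['attempts']} "
      f"successes={report.totals['successes']} "
      f"errors={report.totals['errors_by_fault']}")
print(f"mean duration {report.mean_duration:.1f} s")

text = sw.serialize_report(report)
print(f"report serializes to {len(text)} bytes of JSON "
      f"(totals re-verified on load: {sw.parse_report(text).totals is not None})")

# Two attempts failed on balance and walking posture. While the patient
# adapts, the therapist widens the lean threshold past sin(7 deg) = 0.122
# and relaxes every error range by 40%.
update = sw.TherapistUpdate(strictness=1.4, balance_epsilon=0.15,
                            note="week 1: loosen while patient adapts")
new_config, new_spec, entry = sw.apply_update(config, spec, update)
print(f"\napplied update {entry['changes']} at {entry['timestamp'][:19]}")

stream = sw.walking_stream(sw.WalkerParams(noise_sd=0.0, seed=2), spec)
stream, _ = sw.inject_fault(stream, "lean", (6.0, 10.0), 7.0)
result, _ = sw.run_attempt(stream, new_spec, template, new_config)
print(f"same 7-degree leaner under the eased config: "
      f"success={result.success}")
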