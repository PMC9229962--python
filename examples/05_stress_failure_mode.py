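"""Reproduce the documented failure mode: wrist extension -> ulnar deviation.

On the real sensor, the contact-area change between wrist extension and
ulnar deviation is small, so that transition is where detection fails.  The
stress option narrows the module-1 level gap for an ulnar-deviation plateau
that directly follows wrist extension; the evaluator then flags exactly the
sequences containing that transition.
"""

from fuzzymotion import all_motion_sequences, run_synthetic_study
from fuzzymotion.vocab import ULNAR_DEVIATION, WRIST_EXTENSION

result = run_synthetic_study(noise_sd=0.0, we_ud_stress=0.9, seed=3)
report = result.report

with_transition = [
    s.name
    for s in all_motion_sequences()
    if any(
        a == WRIST_EXTENSION and b == ULNAR_DEVIATION
        for a, b in zip([m for m, _ in s.segments], [m for m, _ in s.segments][1:])
    )
]

print(f"sequences containing a WE->UD transition: {with_transition}")
print(f"flagged failure sequences:                {report.failure_sequences}")
print("failure events:")
for ev in report.failure_events:
    print(f"  {ev.sequence_id}: {ev.true_state} plateau misclassified "
          f"{ev.start_s:.2f}-{ev.end_s:.2f} s")
print(f"\nulnar deviation rate1 = {report.accuracy_rate_1[ULNAR_DEVIATION]:.2f}% "
      f"(failures included), rate2 = {report.accuracy_rate_2[ULNAR_DEVIATION]:.2f}% "
      f"(failure sequences excluded)")
print("\nFailures appear only where ulnar deviation follows wrist extension.")
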