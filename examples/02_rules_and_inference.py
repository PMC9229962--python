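"""One inference step: activate rules, defuzzify, decide the motion.

Fuzzifies a voltage pair that sits between the rest and ulnar-deviation
signatures, fires the matching rules from the 36-entry base, and shows the
weighted-average scores behind the decision.
"""

from fuzzymotion import (
    activate,
    build_grid,
    decide,
    default_calibration,
    default_rule_table,
    defuzzify,
    fuzzify,
)
from fuzzymotion.vocab import MOTION_STATES

grid = build_grid(default_calibration())
table = default_rule_table()

v1, v2 = 0.4, 0.05  # module 1 drifting toward the Low peak, module 2 near rest
w1, w2 = fuzzify(v1, grid), fuzzify(v2, grid)

acts = fired = activate(w1, w2, table)
print(f"inputs: module1 = {v1} V, module2 = {v2} V")
print(f"{len(fired)} rules fire:")
for act in fired:
    print(
        f"  rule {act.rule.index:2d} ({act.rule.label_1}, {act.rule.label_2}) "
        f"m = {act.m:.2f}  strengths = {act.rule.strengths}"
    )

scores = defuzzify(acts)
print("\ndefuzzification scores (each in [0.5, 2]):")
for state, score in zip(MOTION_STATES, scores):
    print(f"  {state:16s} {score:.4f}")
print(f"\ndecision: {decide(scores)}")
print("The largest score wins; Low/Off voltages here favour ulnar deviation.")
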