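"""Fuzzify single voltages through a calibrated membership function.

Builds the six-triangle input membership function from the demo anchors
(x_n = -1 V, x_o = 0 V, x_p = +1 V) and shows how a few voltages split into
weighted fuzzy labels.
"""

from fuzzymotion import build_grid, default_calibration, fuzzify, weights_as_dict

calib = default_calibration()
grid = build_grid(calib)

print(f"anchors: x_n={calib.x_n}, x_o={calib.x_o}, x_p={calib.x_p}")
print(f"triangle peaks (V): {grid.peaks}")
print(f"saturation boundaries: b1={grid.outer_neg}, b2={grid.outer_pos}\n")

for v in [0.0, 0.25, 0.9, 1.8, -1.2]:
    weights = {k: w for k, w in weights_as_dict(fuzzify(v, grid)).items() if w > 0}
    print(f"v = {v:+.2f} V  ->  {weights}")

print(
    "\nEach voltage activates at most two adjacent labels whose weights sum"
    "\nto 1; beyond the outer boundaries a single label saturates at 1."
)
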