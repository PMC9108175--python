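"""Recover a known device miscalibration from still periods.

Builds a static-rich signal (many wrist orientations), distorts it with
per-axis gain and offset errors, and shows the sphere-fit autocalibration
recovering the distortion.
"""

import numpy as np

from wristcut import autocalibrate

rng = np.random.default_rng(0)
segments = []
for _ in range(40):  # 40 still postures, 15 s each at 30 Hz
    u = rng.standard_normal(3)
    u /= np.linalg.norm(u)
    segments.append(u + 0.002 * rng.standard_normal((450, 3)))
raw = np.concatenate(segments)

gain = np.array([1.04, 0.97, 1.02])
offset = np.array([0.02, -0.03, 0.01])
cal = autocalibrate(raw * gain + offset)

g_imp, o_imp = cal.implied_distortion
print(f"true gain    {gain}\nrecovered    {np.round(g_imp, 4)}")
print(f"true offset  {offset}\nrecovered    {np.round(o_imp, 4)}")
print(f"converged: {cal.converged}, residual {cal.residual * 1000:.2f} mg")
print("\nRecovered parameters match the injected distortion to ~1e-3, so")
print("ENMO computed after calibration is unbiased by device error.")
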