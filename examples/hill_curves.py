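"""Evaluate the Hill constitutive curves of a horizontal rectus global layer.

Prints the active force-length curve, the force-velocity curve, and the
passive tension at a few normalized operating points.  FL peaks at 1 at the
optimal fibre length; FV is 1 isometrically, 0 at the maximal shortening
velocity, and saturates at 1.4 for fast lengthening; passive tension is an
exponential toe above the slack length.
"""

import numpy as np

from oculoplant import force_length, force_velocity, make_default_anatomy, muscle_tension

params = make_default_anatomy().muscles["LR"].gl_params

print("active force-length (normalized length -> FL):")
for ln in (0.7, 0.85, 1.0, 1.15, 1.3):
    print(f"  l/l0 = {ln:4.2f}   FL = {force_length(ln, params.fl_width):.3f}")

print("force-velocity (normalized velocity -> FV; negative = shortening):")
for vn in (-1.0, -0.5, -0.25, 0.0, 0.5, 2.0):
    print(f"  v/vmax = {vn:5.2f}  FV = {force_velocity(vn):.3f}")

print("total tension at half activation (gf):")
for stretch in (0.95, 1.0, 1.1):
    state = muscle_tension(params, 0.5, stretch * params.optimal_fiber_length, 0.0)
    print(
        f"  l = {stretch:4.2f} l0:  active {state.f_active:6.2f}"
        f"  passive {state.f_passive:6.2f}  total {state.f_muscle:6.2f}"
    )
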