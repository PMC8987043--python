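"""Pulley stability in vertical ductions.

Solves static fixations at 30 deg supraduction, central gaze and 30 deg
infraduction, then reports the transverse sideslip of the LR and MR pulleys
(the orbital-layer insertion points on their tubes) and the inflection of
the muscle paths at the pulleys.  A stable pulley shows sub-half-millimetre
sideslip while the anterior path inflects by about half the gaze angle —
the half-angle kinematics of the pulley apparatus.  Runs ~0.5-1 min.
"""

from oculoplant import make_default_anatomy, measure_inflection_angle, measure_sideslip, run_duction_sweep
from oculoplant.globe_dynamics import Plant

config = make_default_anatomy()
plant = Plant(config)
sweep = run_duction_sweep(
    config, "vertical", [-30.0, 0.0, 30.0], plant=plant, keep_states=True
)

for muscle in ("LR", "MR"):
    slips = measure_sideslip(sweep, muscle)
    print(f"{muscle} pulley transverse sideslip (mm, + = superior):")
    for angle, slip in slips.items():
        print(f"  {angle:+6.1f} deg vertical gaze: {slip:+.3f} mm")
    for angle in (-30.0, 30.0):
        infl = measure_inflection_angle(plant, sweep.states[angle], muscle)
        print(f"  path inflection at {angle:+.0f} deg: {infl:.1f} deg "
              f"(half-angle would be 15.0)")
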