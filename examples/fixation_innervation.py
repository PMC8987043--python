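"""Innervation and tension of the horizontal recti across horizontal gaze.

Solves static fixations at 30 deg adduction, central gaze, and 30 deg
abduction, and prints the layer innervations and insertional tensions.
The orbital layer (OL) of each contracting rectus is innervated at least
0.05 above its global layer (GL); agonist tension rises into the field of
action while the relaxed antagonist is carried by passive stretch.
Runs ~1 min.
"""

from oculoplant import make_default_anatomy, run_duction_sweep
from oculoplant.globe_dynamics import Plant

config = make_default_anatomy()
plant = Plant(config)
sweep = run_duction_sweep(config, "horizontal", [-30.0, 0.0, 30.0], plant=plant)

for _, row in sweep.records.iterrows():
    h = row["angle_deg"]
    label = "adduction" if h < 0 else ("abduction" if h > 0 else "central")
    print(f"gaze {h:+5.1f} deg ({label}):")
    print(
        f"  innervation  LR GL/OL = {row['a_LR_GL']:.3f}/{row['a_LR_OL']:.3f}"
        f"   MR GL/OL = {row['a_MR_GL']:.3f}/{row['a_MR_OL']:.3f}"
    )
    print(
        f"  insertional tension  LR = {row['tension_LR_gf']:.1f} gf"
        f"   MR = {row['tension_MR_gf']:.1f} gf"
    )
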