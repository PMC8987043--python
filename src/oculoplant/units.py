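"""Unit conventions and constants.

The package works in the units customary in the oculomotor literature:

- length:  millimetres (mm)
- force:   gram-force (gf); 1 gf = 9.80665 mN
- torque:  gf.mm
- mass:    grams (g)
- time:    seconds (s)
- angles:  degrees at every API surface; radians only inside integrators
- gaze:    Fick sequence (horizontal, then vertical); for the modelled right
           eye, positive horizontal = abduction (temporal), positive vertical
           = supraduction. "30 deg adduction" is therefore gaze_h = -30.

``G0`` converts gram-force into the g.mm/s^2 system used by the integrator:
a force of F gf accelerates a mass of m g at F * G0 / m mm/s^2.
"""

import numpy as np

#: standard gravity in mm/s^2 (1 gf = G0 g.mm/s^2)
G0 = 9806.65

DEG2RAD = np.pi / 180.0
RAD2DEG = 180.0 / np.pi
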