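"""Physical constants for lutetium-177 dosimetry."""

import math

LN2 = math.log(2.0)

#: Physical half-life of 177Lu in hours (6.647 d).
LU177_HALF_LIFE_H = 6.647 * 24.0

#: Physical decay constant of 177Lu (1/h).
LU177_DECAY_RATE_PER_H = LN2 / LU177_HALF_LIFE_H

#: Converts an electron energy per decay (keV) into Gy.g.MBq^-1.h^-1 under
#: local energy deposition: 1 keV = 1.602e-16 J, 1 MBq.h = 3.6e9 decays,
#: 1 g = 1e-3 kg.  147.9 keV -> 0.0853 Gy.g/(MBq.h).
KEV_TO_GY_G_PER_MBQ_H = 1.602176634e-16 * 3.6e9 / 1e-3
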