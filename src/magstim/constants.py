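"""Physical constants used by the field engine."""

import math

#: vacuum permeability, T*m/A
MU_0 = 4.0e-7 * math.pi
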