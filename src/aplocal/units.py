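"""Unit conventions and conversion constants.

Geometry is held internally in nanometres; electrotonic (length / sqrt(radius))
quantities in nm^(1/2).  Reported values are converted to metres, m^(1/2) and
micrometres.  The hemibrain pixel dialect (1 pixel = 8 nm) is kept as a named
constant so that pixel-coordinate thresholds can be expressed exactly.
"""

import math

#: nm per hemibrain voxel/pixel coordinate unit
NM_PER_PIXEL = 8.0

#: metres per nanometre
M_PER_NM = 1e-9

#: m^(1/2) per nm^(1/2): electrotonic lengths scale with the square root of
#: geometric length, so the conversion factor is sqrt(1e-9).
M12_PER_NM12 = math.sqrt(M_PER_NM)

#: nm per micrometre
NM_PER_UM = 1e3

M_PER_UM = 1e-6


def nm_to_m(x):
    return x * M_PER_NM


def nm12_to_m12(x):
    """Convert an electrotonic length from nm^(1/2) scale to m^(1/2) scale."""
    return x * M12_PER_NM12


def um_to_nm(x):
    return x * NM_PER_UM
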