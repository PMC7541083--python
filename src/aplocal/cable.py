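"""Passive-cable parameter conversions.

For a passive cylindrical cable the space constant is
lambda = sqrt(r * Rm / (2 * Ra)) with r the neurite radius, Rm the specific
membrane resistance (Ohm m^2) and Ra the specific axial resistance (Ohm m).
Factoring out sqrt(r) gives the radius-independent space constant in
electrotonic space, k = sqrt(Rm / (2 Ra)) (m^(1/2)), which relates to the
real-space constant through a skeleton-wide conversion ratio:

    lambda = k * (total real length / total electrotonic length)

so measured lambdas convert to membrane parameters and back.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .inhibition import APL_CONVERSION_RATIO_M12
from .units import M_PER_UM

__all__ = ["CableParams", "cable_to_space_constant", "lambda_to_cable"]


@dataclass(frozen=True)
class CableParams:
    """Consistent bundle of cable parameters.

    Attributes
    ----------
    Rm_over_Ra : float
        Membrane-to-axial specific resistance ratio (m).
    k_m12 : float
        Space constant in electrotonic space, sqrt(Rm / (2 Ra)) (m^(1/2)).
    lambda_um : float
        Space constant in real space (um).
    conversion_ratio_m12 : float
        Skeleton length / electrotonic length (m^(1/2)); lambda = k * ratio.
    """

    Rm_over_Ra: float
    k_m12: float
    lambda_um: float
    conversion_ratio_m12: float

    def __post_init__(self):
        for name in ("Rm_over_Ra", "k_m12", "lambda_um", "conversion_ratio_m12"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def cable_to_space_constant(
    Rm_over_Ra, conversion_ratio_m12=APL_CONVERSION_RATIO_M12
) -> CableParams:
    """Space constants implied by a membrane/axial resistance ratio (m)."""
    if Rm_over_Ra <= 0 or conversion_ratio_m12 <= 0:
        raise ValueError("inputs must be positive")
    k = math.sqrt(Rm_over_Ra / 2.0)
    lam_um = k * conversion_ratio_m12 / M_PER_UM
    return CableParams(Rm_over_Ra, k, lam_um, conversion_ratio_m12)


def lambda_to_cable(lambda_um, conversion_ratio_m12=APL_CONVERSION_RATIO_M12) -> CableParams:
    """Membrane parameters implied by a real-space space constant (um)."""
    if lambda_um <= 0 or conversion_ratio_m12 <= 0:
        raise ValueError("inputs must be positive")
    k = lambda_um * M_PER_UM / conversion_ratio_m12
    return CableParams(2.0 * k * k, k, lambda_um, conversion_ratio_m12)
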