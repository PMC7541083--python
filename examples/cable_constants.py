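"""Convert between space constants and membrane parameters.

The APL skeleton's total real length (0.08018 m) and total electrotonic
length (179 m^1/2) fix the ratio between the real-space space constant
lambda and its electrotonic counterpart k = sqrt(Rm / 2 Ra).  From that one
ratio, any of lambda, k or Rm/Ra determines the other two.
"""

from aplocal import cable_to_space_constant, lambda_to_cable
from aplocal.inhibition import APL_CONVERSION_RATIO_M12

print(f"lambda/k conversion ratio: {APL_CONVERSION_RATIO_M12:.4g} m^1/2")

p = lambda_to_cable(50.0)
print(f"lambda = 50 um  ->  k = {p.k_m12:.4f} m^1/2, Rm/Ra = {p.Rm_over_Ra:.4f} m")

for rm_ra in (0.0907, 2.0):
    p = cable_to_space_constant(rm_ra)
    print(f"Rm/Ra = {rm_ra:g} m  ->  k = {p.k_m12:.3f} m^1/2, lambda = {p.lambda_um:.1f} um")

# The first line is how measured dye spread (~50 um) translates into a
# membrane-to-axial resistance ratio; the last two are the lambdas implied by
# published Drosophila membrane parameters.
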