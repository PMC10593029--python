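"""The conditional-VE identity and why VE_H|S can rise as protection wanes.

VE_H|S = 1 - (1 - VE_SH) / (1 - VE_S) is exact algebra.  Because it is a
ratio of two waning quantities, the conditional measure can move either
way: Example 1 (similar waning rates) falls from 70% to 43%, Example 2
(protection against infection wanes much faster) *rises* from 63% to 71%.
"""

from param_lab import percent, ve_compose, ve_conditional
from param_lab.experiments import reproduce_table2

print(reproduce_table2().to_string(index=False))

# the identity round-trips exactly
ve_s, ve_sh = 0.65, 0.80
ve_h_s = ve_conditional(ve_s, ve_sh)
print(f"\nVE_H|S(VE_S={ve_s}, VE_SH={ve_sh}) = {ve_h_s:.6f} ({percent(ve_h_s)}%)")
print(f"recomposed VE_SH = {ve_compose(ve_s, ve_h_s):.6f} (identity)")
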