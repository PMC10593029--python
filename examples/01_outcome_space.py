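"""Enumerate the feasible post-exposure outcome space.

Six binary events (infection, symptoms, diagnosis, hospitalization, ICU,
death) admit 64 unconstrained outcome vectors; precedence constraints
shrink the space.  The shipped default lets death skip the ICU, so the
feasible count lands between the strict-chain minimum (7) and 64.
"""

from param_lab import default_chain, enumerate_feasible, strict_chain, unconstrained_chain

for name, chain in [
    ("unconstrained", unconstrained_chain()),
    ("strict linear", strict_chain()),
    ("default (death may skip ICU)", default_chain()),
]:
    feasible = enumerate_feasible(chain)
    print(f"{name:30s} {len(feasible):3d} feasible outcomes")

print("\nfeasible vectors of the default chain (I,S,D,H,C,M):")
for v in enumerate_feasible(default_chain()):
    print(" ", v.values)
# Note (1,1,1,1,0,1): death without ICU admission is allowed, while any
# vector with an event but no infection is not.
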