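"""Hetero-oligomer oxidation kinetics: two chains, four exponential phases.

In a Tsa1-Tsa2 hetero-decamer the two subunit types react with H2O2 at
different second-order rates but share the conformational-change and
disulfide-formation steps.  The fluorescence trace is therefore a sum of
four exponentials: two H2O2-dependent fast phases and two shared slow
phases.  This script simulates that situation and recovers all four
constants by quadruple-exponential fitting plus a secondary plot.
"""

from prxkit import hetero_oxidation_recovery

res = hetero_oxidation_recovery(seed=1)
gen = res["generating"]
print("hetero-oligomer oxidation (generating -> recovered):")
print(f"  k1oxA (faster subunit): {gen['k1oxA']:.3g} -> {res['k1oxA']:.3g} M^-1 s^-1")
print(f"  k1oxB (slower subunit): {gen['k1oxB']:.3g} -> {res['k1oxB']:.3g} M^-1 s^-1")
print(f"  shared k2ox:            {gen['k2ox']:.3g} -> {res['k2ox']:.3g} s^-1")
print(f"  shared k3ox:            {gen['k3ox']:.3g} -> {res['k3ox']:.3g} s^-1")
print("\nThe two fast rates are within threefold of each other, so their",
      "separation is the hardest part of the fit; the shared phases are",
      "recovered almost exactly.")
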