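"""Hydration resistance of red-cabbage anthocyanins.

Anthocyanins fade when water adds at C2 of the flavylium core; the
apparent hydration constant pK'h is the pH at which colored and colorless
forms are equimolar — higher means better color retention.  This script
simulates noisy equilibrium titrations for four pigments and refits pK'h,
showing that monoacylated P2 is an outlier in hydration resistance.
"""

from anthochrome.equilibria import fit_pkh
from anthochrome.synthetic import TITRATION_LIBRARY, make_titration_fixture

header = "fitted pK'h"
print(f"{'pigment':<8} {'truth':>6} {header:>12} {'stderr':>8}")
for name in ("P1", "P5", "P8", "P2"):
    series = make_titration_fixture(name, seed=42)
    fit = fit_pkh(series)
    truth = TITRATION_LIBRARY[name].pKh_prime
    print(f"{name:<8} {truth:>6.1f} {fit.pKh_prime:>12.3f} {fit.pKh_stderr:>8.4f}")

print("\nAcylation normally adds ~0.6-1.6 pK'h units (P1 → P5 → P8);")
print("P2 exceeds even the diacylated P8 despite carrying a single sinapoyl,")
print("because its folded conformation shields C2 from water.")
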