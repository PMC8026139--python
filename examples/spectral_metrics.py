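"""Spectral metrics of four blue colorants.

Generates the fixture absorbance spectra of the four blues (synthetic
brilliant blue, spirulina phycocyanin, red-cabbage anthocyanins at pH 8,
and the Al3+(P2-)3 complex at pH 7), then reports λmax and the violet
contribution (VC, left-Riemann area of absorbance over 500-600 nm).  A
cyan suitable for blending needs a long λmax *and* a small VC; the shift
of P2's λmax on Al3+ addition shows why the complex achieves both.
"""

from anthochrome.spectra import bathochromic_shift, find_lambda_max, violet_contribution
from anthochrome.synthetic import make_spectrum_fixture

print(f"{'sample':<12} {'λmax (nm)':>10} {'VC (nm·AU)':>12}")
for name in ("blue_no1", "spirulina", "rca_pH8", "alp2_pH7"):
    s = make_spectrum_fixture(name)
    m = find_lambda_max(s)
    print(f"{name:<12} {m.lambda_max_nm:>10.0f} {violet_contribution(s):>12.1f}")

shift = bathochromic_shift(
    make_spectrum_fixture("P2_0eq"), make_spectrum_fixture("P2_Al13")
)
print(f"\nP2 + 1/3 eq Al3+ bathochromic shift: +{shift:.0f} nm")
print("A positive shift >40 nm moves P2 from violet-blue into the cyan band;")
print("the complex pairs the longest λmax with the smallest violet leakage.")
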