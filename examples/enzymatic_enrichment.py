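"""Enzymatic enrichment of P2 from the red-cabbage peak series.

P2 is a minor component (<5% of peak area) of red cabbage, but the
acylated peaks P3-P8 share its scaffold.  An esterase cleaving acyl groups
from Glc-1 funnels P6-P8 into P2 (and P3-P5 into P1).  This script
integrates the untreated and enzyme-treated fixture chromatograms and
reports the conversion metrics.
"""

from anthochrome.chromatography import (
    assign_peaks,
    conversion_metrics,
    detect_peaks,
    integrate_peaks,
)
from anthochrome.synthetic import REFERENCE_PEAK_TIMES, make_rca_chromatogram


def analysed(treatment):
    c = make_rca_chromatogram(treatment, seed=1)
    return assign_peaks(
        integrate_peaks(c, detect_peaks(c)), REFERENCE_PEAK_TIMES
    )


before = analysed("untreated")
after = analysed("M73H_complete")

print("untreated relative areas (%):")
print(before[["peak_id", "apex_time_min", "relative_area_pct"]]
      .to_string(index=False, float_format=lambda v: f"{v:.2f}"))

m = conversion_metrics(before, after)
print(f"\nP2 before treatment: "
      f"{float(before.loc[before.peak_id == 'P2', 'relative_area_pct'].iloc[0]):.1f}%")
print(f"acylated peaks (P3-P8) converted: {m['fraction_P3toP8_converted']:.4f}")
print(f"P1+P2 after treatment: {m['P1_plus_P2_relative_area_after_pct']:.1f}%")
print(f"conversion complete (>=99%): {m['complete']}")
print("\nThe engineered esterase turns a 4% minor peak into the dominant")
print("product, which is what makes gram-scale isolation of P2 practical.")
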