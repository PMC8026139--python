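"""Sequence diversity of the esterase activity screen.

Generates a synthetic screened panel (46 tested enzymes, 17 active ones
forming a divergent family), computes the all-pairs identity matrix from
global alignments, and summarises the medians.  The point of the numbers:
activity on the anthocyanin substrate is scattered across very dissimilar
sequences, yet the active subset is measurably more self-similar than the
screen as a whole.
"""

from anthochrome.seqscreen import identity_matrix, median_identity, screen_summary
from anthochrome.synthetic import make_sequence_panel

panel = make_sequence_panel(n=46, n_active=17, seed=7)
matrix = identity_matrix(panel)
active_ids = [r.id for r in panel if r.active]

summary = screen_summary(panel)
print(f"tested: {summary['n_tested']}, active: {summary['n_active']} "
      f"(fraction {summary['fraction_active']})")
print(f"median identity, all tested pairs: {median_identity(matrix):.1f}%")
print(f"median identity, active pairs:     "
      f"{median_identity(matrix, active_ids):.1f}%")
print("\nIdentity is counted over the full global-alignment length including")
print("gap columns, the convention that gives single/low-double-digit values")
print("for panels spanning many unrelated hydrolase families.")
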