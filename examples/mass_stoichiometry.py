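"""Exact-mass stoichiometry of the aluminum-anthocyanin complex.

Builds the monoacylated anthocyanin P2 from its building blocks (cyanidin
core + 3 glucosyl + 1 sinapoyl), computes its exact mass, and then asks
which ligand count k explains the two multivalent negative-mode ESI-TOF
peaks observed for the P2/Al solution.  The enumeration over (k, n, z)
matches both peaks only with k = 3: a 1:3 metal:ligand complex.
"""

from anthochrome.masscalc import (
    BUILDING_BLOCKS,
    assign_stoichiometry,
    compose_anthocyanin,
    monoisotopic_mass,
)

p2 = compose_anthocyanin(BUILDING_BLOCKS["P2"])
print(f"P2 flavylium cation: {p2.to_string()}")
print(f"monoisotopic m/z (z=+1): {monoisotopic_mass(p2):.4f}")

observed = [1478.8629, 985.5760]
result = assign_stoichiometry(observed, p2, metal="Al", tol_ppm=10.0)
print(f"\nobserved peaks: {observed}")
print(result.table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(f"\nconsensus ligand count k = {result.consensus_k}")
print("Both peaks are explained only by three P2 ligands around one Al3+,")
print("i.e. the propeller-shaped Al3+(P2-)3 complex (n = hydrogens removed).")
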