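"""Molecular-formula algebra, monoisotopic masses, and metal-complex
stoichiometry assignment for anthocyanin ESI-TOF-MS data.

Anthocyanin building-block arithmetic: a cyanidin flavylium core
(C15H11O6⁺) is extended by glycosyl and hydroxycinnamoyl residues, each
condensation implicitly releasing one water, so the residues enter as
C6H10O5 (glucosyl), C9H6O2 (p-coumaroyl), C10H8O3 (feruloyl) and C11H10O4
(sinapoyl).  Metal complexes [k·L + M − n·H]^z are matched to observed m/z
by enumerating ligand count k, hydrogen loss n and charge z; because
bracket notations are ambiguous about whether the ligand is counted as a
cation or a neutral base, n is treated as a free search variable and the
match is made purely on mass.

Electron mass is included in all ion masses (subtracted per positive
charge, added per negative charge) — at 10-ppm tolerance near m/z 1000
the electron is not negligible.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "MolecularFormula",
    "AnthocyaninSpec",
    "ComplexIonSpec",
    "RESIDUES",
    "CYANIDIN_CORE",
    "BUILDING_BLOCKS",
    "compose_anthocyanin",
    "monoisotopic_mass",
    "complex_ion_mz",
    "assign_stoichiometry",
    "AssignmentResult",
]

#: Most-abundant-isotope masses (Da), CODATA/IUPAC values.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "Al": 26.98153863,
    "Na": 22.98976928,
    "K": 38.96370668,
    "Fe": 55.93493633,
    "Mg": 23.98504170,
}

ELECTRON_MASS: float = 0.00054857990907  # Da

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element counts plus a signed charge, with exact addition/subtraction."""

    element_counts: dict[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        counts = {e: int(c) for e, c in self.element_counts.items() if c != 0}
        if not counts:
            raise ValueError("formula must contain at least one element")
        if any(c < 0 for c in counts.values()):
            neg = {e: c for e, c in counts.items() if c < 0}
            raise ValueError(f"negative element counts: {neg}")
        object.__setattr__(self, "element_counts", counts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self.element_counts)
        for e, c in other.element_counts.items():
            counts[e] = counts.get(e, 0) + c
        return MolecularFormula(counts, self.charge + other.charge)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self.element_counts)
        for e, c in other.element_counts.items():
            counts[e] = counts.get(e, 0) - c
        return MolecularFormula(counts, self.charge - other.charge)

    def __mul__(self, k: int) -> "MolecularFormula":
        return MolecularFormula(
            {e: c * k for e, c in self.element_counts.items()}, self.charge * k
        )

    __rmul__ = __mul__

    @classmethod
    def from_string(cls, text: str) -> "MolecularFormula":
        """Parse e.g. ``"C44H51O25+1"`` or ``"H2O"`` (trailing signed charge)."""
        m = re.fullmatch(r"([A-Za-z0-9]+)([+-]\d+)?", text.strip())
        if not m:
            raise ValueError(f"cannot parse formula {text!r}")
        body, charge_s = m.groups()
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(body):
            if match.start() != pos or not match.group(1):
                break
            pos = match.end()
            el, num = match.group(1), match.group(2)
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element {el!r} in {text!r}")
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        if pos != len(body):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts, int(charge_s) if charge_s else 0)

    def to_string(self) -> str:
        order = ["C", "H"] + sorted(e for e in self.element_counts if e not in "CH")
        body = "".join(
            f"{e}{self.element_counts[e]}" if self.element_counts[e] != 1 else e
            for e in order
            if e in self.element_counts
        )
        if self.charge:
            body += f"{self.charge:+d}"
        return body


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Monoisotopic mass in Da, corrected for missing/extra electrons."""
    try:
        atoms = sum(MONOISOTOPIC_MASS[e] * c for e, c in f.element_counts.items())
    except KeyError as exc:
        raise ValueError(f"element {exc.args[0]!r} not in the bundled mass table")
    return atoms - f.charge * ELECTRON_MASS


# --- anthocyanin building blocks -------------------------------------------

#: Cyanidin flavylium cation.
CYANIDIN_CORE = MolecularFormula({"C": 15, "H": 11, "O": 6}, charge=+1)

#: Residue formulas as they enter a condensed structure (one water already
#: removed per glycosylation/acylation).
RESIDUES: dict[str, MolecularFormula] = {
    "glucosyl": MolecularFormula({"C": 6, "H": 10, "O": 5}),
    "p-coumaroyl": MolecularFormula({"C": 9, "H": 6, "O": 2}),
    "feruloyl": MolecularFormula({"C": 10, "H": 8, "O": 3}),
    "sinapoyl": MolecularFormula({"C": 11, "H": 10, "O": 4}),
}

_ACYL_POSITIONS = {"Glc-1", "Glc-2"}


@dataclass(frozen=True)
class AnthocyaninSpec:
    """Building-block description of a red-cabbage anthocyanin.

    ``acyl_groups`` is a tuple of (residue name, position) pairs, position
    in {"Glc-1", "Glc-2"} (sugar 1 or 2 of the sophorose).
    """

    core: str = "cyanidin"
    n_glucosyl: int = 3
    acyl_groups: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.core != "cyanidin":
            raise ValueError(f"unknown chromophore {self.core!r}")
        if self.n_glucosyl < 1:
            raise ValueError("n_glucosyl must be >= 1")
        for name, pos in self.acyl_groups:
            if name not in RESIDUES or name == "glucosyl":
                raise ValueError(f"unknown acyl residue {name!r}")
            if pos not in _ACYL_POSITIONS:
                raise ValueError(f"invalid acyl position {pos!r}")


def compose_anthocyanin(spec: AnthocyaninSpec) -> MolecularFormula:
    """Formula of the flavylium cation assembled from building blocks."""
    f = CYANIDIN_CORE + spec.n_glucosyl * RESIDUES["glucosyl"]
    for name, _pos in spec.acyl_groups:
        f = f + RESIDUES[name]
    return f


#: The red-cabbage peaks used throughout: tri-glucosylated cyanidins
#: differing only in hydroxycinnamoyl count and position.
BUILDING_BLOCKS: dict[str, AnthocyaninSpec] = {
    "P1": AnthocyaninSpec(n_glucosyl=3),
    "P2": AnthocyaninSpec(n_glucosyl=3, acyl_groups=(("sinapoyl", "Glc-2"),)),
    "P5": AnthocyaninSpec(n_glucosyl=3, acyl_groups=(("sinapoyl", "Glc-1"),)),
    "P8": AnthocyaninSpec(
        n_glucosyl=3, acyl_groups=(("sinapoyl", "Glc-1"), ("sinapoyl", "Glc-2"))
    ),
}


# --- complex ions -----------------------------------------------------------


@dataclass(frozen=True)
class ComplexIonSpec:
    """[k·L + M − n·H]^z — a multivalent metal–ligand ion.

    The ligand formula contributes atoms only; its nominal charge is
    ignored and the observed charge ``z`` alone fixes the electron count.
    """

    ligand: MolecularFormula
    k_ligands: int = 1
    metal: str | None = None
    n_hydrogens_removed: int = 0
    z: int = -1

    def __post_init__(self) -> None:
        if self.k_ligands < 1:
            raise ValueError("k_ligands must be >= 1")
        if self.n_hydrogens_removed < 0:
            raise ValueError("n_hydrogens_removed must be >= 0")
        if self.z == 0:
            raise ValueError("charge z must be non-zero")
        if self.metal is not None and self.metal not in MONOISOTOPIC_MASS:
            raise ValueError(f"metal {self.metal!r} not in the bundled mass table")

    def composition(self) -> MolecularFormula:
        counts = {
            e: c * self.k_ligands for e, c in self.ligand.element_counts.items()
        }
        if self.metal is not None:
            counts[self.metal] = counts.get(self.metal, 0) + 1
        counts["H"] = counts.get("H", 0) - self.n_hydrogens_removed
        if counts.get("H", 0) < 0:
            raise ValueError(
                f"removing {self.n_hydrogens_removed} H leaves a negative "
                "hydrogen count"
            )
        return MolecularFormula(counts, charge=self.z)


def complex_ion_mz(spec: ComplexIonSpec) -> float:
    """m/z of the complex ion, electron-corrected, divided by |z|."""
    return monoisotopic_mass(spec.composition()) / abs(spec.z)


@dataclass(frozen=True)
class AssignmentResult:
    """Ranked (k, n, z) assignments and the consensus ligand count."""

    table: pd.DataFrame
    consensus_k: int | None

    def to_records(self) -> list[dict]:
        return self.table.to_dict(orient="records")


def assign_stoichiometry(
    observed_mz: list[float],
    ligand: MolecularFormula,
    metal: str | None,
    tol_ppm: float = 10.0,
    k_range: range = range(1, 7),
    z_values: tuple[int, ...] = (-4, -3, -2, -1, 1, 2, 3, 4),
    n_range: range = range(0, 13),
) -> AssignmentResult:
    """Enumerate (k, n, z) and match observed m/z within ``tol_ppm``.

    Every combination in the search space is scored as
    ppm = 1e6·(m/z_calc − m/z_obs)/m/z_obs; matches within tolerance are
    returned ranked by |ppm|.  The consensus ligand count is the unique k
    that matches *every* observed peak; if no k or several k do, the
    consensus is ``None``.  An empty table (no match at all) is a result,
    not an error.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    rows = []
    for mz_obs in observed_mz:
        for k, z, n in itertools.product(k_range, z_values, n_range):
            try:
                spec = ComplexIonSpec(ligand, k, metal, n, z)
                mz_calc = complex_ion_mz(spec)
            except ValueError:
                continue
            ppm = 1e6 * (mz_calc - mz_obs) / mz_obs
            if abs(ppm) <= tol_ppm:
                rows.append(
                    {
                        "observed_mz": mz_obs,
                        "k": k,
                        "n": n,
                        "z": z,
                        "mz_calc": mz_calc,
                        "ppm_error": ppm,
                    }
                )
    table = pd.DataFrame(
        rows, columns=["observed_mz", "k", "n", "z", "mz_calc", "ppm_error"]
    )
    if len(table):
        table = table.reindex(
            table["ppm_error"].abs().sort_values(kind="stable").index
        ).reset_index(drop=True)
    consensus: int | None = None
    if len(table):
        per_peak = table.groupby("observed_mz")["k"].agg(set)
        if len(per_peak) == len(observed_mz):
            common = set.intersection(*per_peak.tolist())
            if len(common) == 1:
                consensus = int(common.pop())
    return AssignmentResult(table=table, consensus_k=consensus)
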