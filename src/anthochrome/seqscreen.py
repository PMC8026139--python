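"""Sequence statistics for the esterase activity screen.

Percent identity between enzyme sequences is computed from pairwise global
(Needleman–Wunsch) alignment — BLOSUM62 with affine gaps for the alignment
path, identity counted as identical columns over the *full alignment
length including gap columns*.  That denominator convention yields the
very low identities (single-digit percent) characteristic of screens that
span many unrelated hydrolase families.  Medians over the tested and
active subsets summarise how sequence-diverse the screen was.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "AMINO_ACIDS",
    "ProteinRecord",
    "AlignmentScheme",
    "IdentityMatrix",
    "pairwise_identity",
    "identity_matrix",
    "median_identity",
    "screen_summary",
    "read_fasta_panel",
    "write_phylip_distances",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET = set(AMINO_ACIDS + "X")


@dataclass(frozen=True)
class ProteinRecord:
    """One screened enzyme: id, sequence, activity call, optional EC class."""

    id: str
    sequence: str
    active: bool | None = None
    ec_class: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence.upper()) - _ALPHABET
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True)
class AlignmentScheme:
    """Global-alignment parameters for the identity computation."""

    substitution_matrix: str = "BLOSUM62"
    open_gap_score: float = -10.0
    extend_gap_score: float = -1.0


def _aligner(scheme: AlignmentScheme) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(
        scheme.substitution_matrix
    )
    aligner.open_gap_score = scheme.open_gap_score
    aligner.extend_gap_score = scheme.extend_gap_score
    return aligner


def pairwise_identity(
    a: ProteinRecord | str,
    b: ProteinRecord | str,
    scheme: AlignmentScheme = AlignmentScheme(),
) -> float:
    """Percent identity over the full global-alignment length (with gaps).

    Deterministic: of the optimal alignments, the aligner's first is used.
    """
    sa = a.sequence if isinstance(a, ProteinRecord) else a.upper()
    sb = b.sequence if isinstance(b, ProteinRecord) else b.upper()
    if not sa or not sb:
        raise ValueError("sequences must be non-empty")
    aln = _aligner(scheme).align(sa, sb)[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length


@dataclass(frozen=True)
class IdentityMatrix:
    """Symmetric percent-identity matrix with a 100 diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape must match id count")
        if not np.allclose(v, v.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 100.0):
            raise ValueError("diagonal must be 100")
        if v.min() < 0 or v.max() > 100 + 1e-9:
            raise ValueError("entries must lie in [0, 100]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def identity_matrix(
    records: list[ProteinRecord], scheme: AlignmentScheme = AlignmentScheme()
) -> IdentityMatrix:
    """All-pairs identity matrix (n(n−1)/2 alignments)."""
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate ids: {dupes}")
    n = len(records)
    m = np.full((n, n), 100.0)
    for i, j in itertools.combinations(range(n), 2):
        v = pairwise_identity(records[i], records[j], scheme)
        m[i, j] = m[j, i] = v
    return IdentityMatrix(ids=tuple(ids), values=m)


def median_identity(m: IdentityMatrix, subset: list[str] | None = None) -> float:
    """Median of the off-diagonal upper-triangle identities in ``subset``.

    An even number of pair values takes the mean of the central pair
    (the ordinary statistical median).
    """
    if subset is None:
        subset = list(m.ids)
    if len(subset) < 2:
        raise ValueError("subset must contain at least 2 ids")
    index = {s: i for i, s in enumerate(m.ids)}
    missing = [s for s in subset if s not in index]
    if missing:
        raise ValueError(f"unknown ids in subset: {missing}")
    rows = [index[s] for s in subset]
    sub = m.values[np.ix_(rows, rows)]
    vals = sub[np.triu_indices(len(rows), k=1)]
    return float(np.median(vals))


def screen_summary(records: list[ProteinRecord]) -> dict:
    """Counts of tested and active enzymes and the active fraction."""
    unknown = [r.id for r in records if r.active is None]
    if unknown:
        raise ValueError(f"activity unknown for: {unknown}")
    n = len(records)
    n_active = sum(1 for r in records if r.active)
    return {
        "n_tested": n,
        "n_active": n_active,
        "fraction_active": round(n_active / n, 3) if n else None,
    }


def read_fasta_panel(
    fasta_path: str | Path, activity_csv: str | Path | None = None
) -> list[ProteinRecord]:
    """Read a FASTA panel, optionally merging an (id, active, ec_class) CSV."""
    activity: dict[str, tuple[bool, str | None]] = {}
    if activity_csv is not None:
        meta = pd.read_csv(activity_csv)
        for _, row in meta.iterrows():
            ec = row.get("ec_class")
            activity[str(row["id"])] = (
                bool(row["active"]),
                None if pd.isna(ec) else str(ec),
            )
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        act, ec = activity.get(rec.id, (None, None))
        records.append(
            ProteinRecord(id=rec.id, sequence=str(rec.seq), active=act, ec_class=ec)
        )
    return records


def write_phylip_distances(m: IdentityMatrix, path: str | Path) -> None:
    """Export 100 − identity as a PHYLIP square distance matrix."""
    dist = 100.0 - m.values
    np.fill_diagonal(dist, 0.0)
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"{len(m.ids)}\n")
        for name, row in zip(m.ids, dist):
            cells = " ".join(f"{v:.4f}" for v in row)
            fh.write(f"{name[:10]:<10} {cells}\n")
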