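"""Pairwise identity, identity matrices and screen statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from Bio.Align import substitution_matrices

from anthochrome.seqscreen import (
    AlignmentScheme,
    IdentityMatrix,
    ProteinRecord,
    identity_matrix,
    median_identity,
    pairwise_identity,
    read_fasta_panel,
    screen_summary,
    write_phylip_distances,
)
from anthochrome.synthetic import make_sequence_panel

_seq = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=8)


def _exhaustive_optimal_alignments(a, b, open_gap=-10.0, extend_gap=-1.0):
    """Enumerate every global alignment of two short sequences under
    BLOSUM62 with affine gaps; return (best score, set of identity
    percentages among optimal alignments)."""
    blosum = substitution_matrices.load("BLOSUM62")
    results = []

    def recurse(i, j, score, identities, length, last):
        if i == len(a) and j == len(b):
            results.append((score, identities, length))
            return
        if i < len(a) and j < len(b):
            s = blosum[a[i], b[j]]
            recurse(i + 1, j + 1, score + s,
                    identities + (a[i] == b[j]), length + 1, "m")
        if i < len(a):
            gap = extend_gap if last == "ga" else open_gap
            recurse(i + 1, j, score + gap, identities, length + 1, "ga")
        if j < len(b):
            gap = extend_gap if last == "gb" else open_gap
            recurse(i, j + 1, score + gap, identities, length + 1, "gb")

    recurse(0, 0, 0.0, 0, 0, None)
    best = max(r[0] for r in results)
    idents = {
        100.0 * r[1] / r[2] for r in results if abs(r[0] - best) < 1e-9
    }
    return best, idents


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        s = "MKTLLVAGGFLAPSTWEQHV"
        assert pairwise_identity(s, s) == 100.0

    def test_single_substitution_gapless(self):
        assert pairwise_identity("ACDEFG", "ACDEYG") == pytest.approx(
            100 * 5 / 6, abs=0.01
        )

    def test_no_shared_letters_zero(self):
        assert pairwise_identity("AAAA", "CCCC") == 0.0

    def test_matches_exhaustive_alignment_oracle(self, rng):
        """Optimal score and identity agree with brute-force enumeration
        of all global alignments on short sequences."""
        from Bio.Align import PairwiseAligner

        aligner = PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -1.0
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(8):
            a = "".join(rng.choice(letters, size=rng.integers(2, 6)))
            b = "".join(rng.choice(letters, size=rng.integers(2, 6)))
            best_score, optimal_idents = _exhaustive_optimal_alignments(a, b)
            assert aligner.score(a, b) == pytest.approx(best_score)
            ident = pairwise_identity(a, b)
            assert any(ident == pytest.approx(v) for v in optimal_idents)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(a=_seq, b=_seq)
    def test_symmetry(self, a, b):
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(s=_seq)
    def test_self_identity_always_100(self, s):
        assert pairwise_identity(s, s) == 100.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            pairwise_identity("", "ACDE")


class TestIdentityMatrix:
    def test_two_identical_sequences(self):
        recs = [
            ProteinRecord("a", "MKTLLVAGG"),
            ProteinRecord("b", "MKTLLVAGG"),
        ]
        m = identity_matrix(recs)
        assert m.values[0, 1] == 100.0

    def test_matches_independent_pairwise_calls(self, rng):
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        recs = [
            ProteinRecord(f"s{i}", "".join(rng.choice(letters, size=30)))
            for i in range(3)
        ]
        m = identity_matrix(recs)
        for i, j in itertools.combinations(range(3), 2):
            assert m.values[i, j] == pytest.approx(
                pairwise_identity(recs[i], recs[j])
            )

    def test_duplicate_ids_rejected(self):
        recs = [ProteinRecord("x", "AAAA"), ProteinRecord("x", "CCCC")]
        with pytest.raises(ValueError, match="duplicate"):
            identity_matrix(recs)

    def test_invalid_matrix_construction_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            IdentityMatrix(("a", "b"), np.array([[100.0, 5.0], [7.0, 100.0]]))


class TestMedianIdentity:
    def test_subset_of_two_is_the_pair_value(self):
        vals = np.array([[100.0, 42.0], [42.0, 100.0]])
        m = IdentityMatrix(("a", "b"), vals)
        assert median_identity(m) == 42.0

    def test_matches_sort_oracle_on_random_matrix(self, rng):
        n = 12
        upper = rng.uniform(0, 100, size=(n, n))
        vals = np.triu(upper, 1)
        vals = vals + vals.T
        np.fill_diagonal(vals, 100.0)
        m = IdentityMatrix(tuple(f"s{i}" for i in range(n)), vals)
        pair_vals = sorted(
            vals[i, j] for i, j in itertools.combinations(range(n), 2)
        )
        k = len(pair_vals)
        oracle = (
            pair_vals[k // 2]
            if k % 2
            else 0.5 * (pair_vals[k // 2 - 1] + pair_vals[k // 2])
        )
        assert median_identity(m) == pytest.approx(oracle)

    def test_unknown_subset_id_rejected(self):
        m = IdentityMatrix(("a", "b"), np.array([[100.0, 5.0], [5.0, 100.0]]))
        with pytest.raises(ValueError, match="unknown ids"):
            median_identity(m, ["a", "zzz"])


@pytest.fixture(scope="module")
def panel_and_matrix():
    panel = make_sequence_panel(n=46, n_active=17, seed=7)
    return panel, identity_matrix(panel)


class TestScreenPanel:
    def test_pair_count(self, panel_and_matrix):
        panel, m = panel_and_matrix
        assert len(panel) == 46
        assert m.values[np.triu_indices(46, k=1)].size == 1035

    def test_active_subset_more_self_similar(self, panel_and_matrix):
        """The active enzymes form a family: their median pairwise
        identity sits above the median over the whole tested panel."""
        panel, m = panel_and_matrix
        active = [r.id for r in panel if r.active]
        assert median_identity(m, active) > median_identity(m)

    def test_screen_summary_counts(self, panel_and_matrix):
        panel, _ = panel_and_matrix
        assert screen_summary(panel) == {
            "n_tested": 46,
            "n_active": 17,
            "fraction_active": 0.370,
        }

    def test_summary_edge_cases(self):
        assert screen_summary([]) == {
            "n_tested": 0, "n_active": 0, "fraction_active": None,
        }
        recs = [ProteinRecord("a", "MK", active=True)]
        assert screen_summary(recs)["fraction_active"] == 1.0
        with pytest.raises(ValueError, match="unknown"):
            screen_summary([ProteinRecord("a", "MK")])

    def test_fasta_round_trip_and_phylip_export(self, tmp_path, panel_and_matrix):
        panel, m = panel_and_matrix
        fasta = tmp_path / "panel.fasta"
        meta = tmp_path / "activity.csv"
        with fasta.open("w") as fh:
            for r in panel[:5]:
                fh.write(f">{r.id}\n{r.sequence}\n")
        with meta.open("w") as fh:
            fh.write("id,active,ec_class\n")
            for r in panel[:5]:
                fh.write(f"{r.id},{r.active},3.1.1\n")
        back = read_fasta_panel(fasta, meta)
        assert [r.sequence for r in back] == [r.sequence for r in panel[:5]]
        assert all(r.active for r in back)

        out = tmp_path / "dist.phy"
        write_phylip_distances(m, out)
        lines = out.read_text().splitlines()
        assert lines[0].strip() == "46"
        first_row = [float(x) for x in lines[1].split()[1:]]
        assert first_row[0] == 0.0
        assert first_row[1] == pytest.approx(100.0 - m.values[0, 1], abs=1e-3)
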