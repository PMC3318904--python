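"""Substitution matrices, query profiles, and the ASCII PSSM reader."""

import numpy as np
import pytest

from psse import (
    MatrixError,
    Sequence,
    build_local_profile,
    load_matrix,
    profile_score,
    read_ascii_pssm,
)
from psse.scoring import PSSM_COLUMN_ORDER, GapPenalties, write_ascii_pssm
from psse.seq_io import PROTEIN_ALPHABET


class TestLoadMatrix:
    def test_blosum62_canonical_values(self, blosum62):
        # spot values from the published BLOSUM62 table
        assert blosum62.score("A", "A") == 4
        assert blosum62.score("W", "W") == 11
        assert blosum62.score("A", "R") == -1
        assert blosum62.score("C", "C") == 9
        assert blosum62.score("W", "C") == -2

    def test_blosum62_shape_and_alphabet(self, blosum62):
        assert blosum62.alphabet == PROTEIN_ALPHABET
        assert blosum62.scores.shape == (24, 24)

    def test_blosum62_symmetric_with_dominant_diagonal(self, blosum62):
        assert blosum62.is_symmetric
        s = blosum62.scores[:20, :20]
        off = s - np.diag(np.diag(s))
        assert all(s[i, i] >= off[i].max() for i in range(20))

    def test_reads_ncbi_format_file(self, tmp_path, blosum62):
        p = tmp_path / "mini.mat"
        p.write_text(
            "# tiny matrix\n   A  R  N\nA  4 -1 -2\nR -1  5  0\nN -2  0  6\n"
        )
        m = load_matrix(str(p))
        assert m.alphabet == "ARN"
        assert m.score("R", "N") == 0

    def test_ragged_matrix_file_rejected(self, tmp_path):
        p = tmp_path / "bad.mat"
        p.write_text("   A  R  N\nA  4 -1 -2  7\nR -1  5  0\nN -2  0  6\n")
        with pytest.raises(MatrixError):
            load_matrix(str(p))


class TestGapPenalties:
    def test_cost_formula_matches_open_plus_extend_per_residue(self):
        g = GapPenalties(open=10, extend=2)
        assert [g.cost(k) for k in (0, 1, 2, 5)] == [0, 12, 14, 20]

    def test_strictly_increasing_when_extending(self):
        g = GapPenalties(open=10, extend=2)
        costs = [g.cost(k) for k in range(1, 10)]
        assert all(b > a for a, b in zip(costs, costs[1:]))

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            GapPenalties(open=-1)


class TestLocalProfile:
    def test_row_of_matching_residue(self, blosum62):
        prof = build_local_profile(Sequence("q", "AAAA"), blosum62)
        assert prof.kind == "local"
        assert list(prof.scores[PROTEIN_ALPHABET.index("A")]) == [4, 4, 4, 4]

    def test_columns_equal_matrix_columns(self, blosum62):
        query = Sequence("q", "WARDN")
        prof = build_local_profile(query, blosum62)
        for i, aa in enumerate(query.residues):
            for b in PROTEIN_ALPHABET:
                assert prof.score(b, i) == blosum62.score(b, aa)

    def test_empty_query_rejected(self, blosum62):
        from psse import SequenceError

        with pytest.raises(SequenceError):
            build_local_profile(Sequence("q", ""), blosum62)

    def test_profile_score_bounds(self, blosum62):
        prof = build_local_profile(Sequence("q", "AAAA"), blosum62)
        assert profile_score(prof, "A", 2) == 4
        with pytest.raises(IndexError):
            prof.score("A", 4)
        with pytest.raises(IndexError):
            prof.score("A", -1)
        with pytest.raises(MatrixError):
            prof.score("J", 0)


class TestAsciiPssm:
    def _write_from_blosum(self, tmp_path, query, blosum62, jitter=None):
        bidx = {a: i for i, a in enumerate(blosum62.alphabet)}
        cols = np.array([bidx[aa] for aa in query.residues])
        rows = np.array([bidx[aa] for aa in PSSM_COLUMN_ORDER])
        scores = blosum62.scores[np.ix_(rows, cols)]
        if jitter is not None:
            scores = scores + jitter
        path = tmp_path / f"{query.id}.pssm"
        write_ascii_pssm(scores, query, path)
        return path

    def test_round_trip_of_synthetic_pssm(self, tmp_path, blosum62):
        query = Sequence("q", "WARD")
        rng = np.random.default_rng(4)
        jitter = rng.integers(-2, 3, size=(20, 4))
        path = self._write_from_blosum(tmp_path, query, blosum62, jitter)
        prof = read_ascii_pssm(path)
        assert prof.kind == "position_specific"
        assert prof.length == 4
        assert prof.query_residues == "WARD"
        bidx = {a: i for i, a in enumerate(blosum62.alphabet)}
        for k, aa in enumerate(PSSM_COLUMN_ORDER):
            for i, q in enumerate(query.residues):
                assert prof.score(aa, i) == blosum62.score(aa, q) + jitter[k, i]

    def test_blosum_pssm_equals_local_profile_on_standard_residues(
        self, tmp_path, blosum62
    ):
        query = Sequence("q", "MKVLHEQ")
        path = self._write_from_blosum(tmp_path, query, blosum62)
        prof = read_ascii_pssm(path)
        local = build_local_profile(query, blosum62)
        assert np.array_equal(prof.scores, local.scores)  # incl. B/Z/X/* fallback

    def test_ambiguity_rows_default_to_blosum62(self, tmp_path, blosum62):
        query = Sequence("q", "AR")
        prof = read_ascii_pssm(self._write_from_blosum(tmp_path, query, blosum62))
        assert prof.score("X", 0) == blosum62.score("X", "A")
        assert prof.score("B", 1) == blosum62.score("B", "R")

    def test_constant_ambiguity_rule(self, tmp_path, blosum62):
        query = Sequence("q", "AR")
        path = self._write_from_blosum(tmp_path, query, blosum62)
        prof = read_ascii_pssm(path, ambiguity="constant", ambiguity_penalty=-5)
        assert prof.score("X", 0) == -5
        assert prof.score("*", 1) == -5

    def test_truncated_file_rejected(self, tmp_path):
        p = tmp_path / "trunc.pssm"
        p.write_text("Last position-specific scoring matrix computed\n   A  R  N\n")
        with pytest.raises(MatrixError, match="no PSSM rows"):
            read_ascii_pssm(p)

    def test_short_row_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "short.pssm"
        header = "            " + "  ".join(PSSM_COLUMN_ORDER) + "\n"
        p.write_text(header + "    1 A   1 2 3\n")
        with pytest.raises(MatrixError, match="line 2"):
            read_ascii_pssm(p)

    def test_out_of_order_rows_rejected(self, tmp_path):
        p = tmp_path / "order.pssm"
        row = " ".join(["1"] * 20)
        p.write_text(f"    2 A  {row}\n")
        with pytest.raises(MatrixError, match="out of order"):
            read_ascii_pssm(p)
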