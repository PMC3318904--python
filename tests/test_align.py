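"""Smith-Waterman scoring: oracle equivalence and structural invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from psse import (
    AlignmentTask,
    GapPenalties,
    Sequence,
    build_local_profile,
    sw_score,
    sw_score_batch,
    sw_score_exhaustive,
)

REDUCED = "ARND"

_BLOSUM = __import__("psse").load_matrix("BLOSUM62")


def random_pair(rng, max_len=8, alphabet=REDUCED):
    ql, sl = rng.integers(1, max_len + 1, size=2)
    q = "".join(rng.choice(list(alphabet), ql))
    s = "".join(rng.choice(list(alphabet), sl))
    return Sequence("q", q), Sequence("s", s)


class TestSwScore:
    def test_perfect_match_sums_diagonal(self, blosum62, gaps):
        task = AlignmentTask(Sequence("q", "AAAA"), Sequence("s", "AAAA"), blosum62, gaps)
        assert sw_score(task) == 16

    def test_local_floor_when_all_scores_nonpositive(self, gaps, tmp_path):
        from psse import load_matrix

        p = tmp_path / "neg.mat"
        p.write_text("   A  R\nA -1 -2\nR -2 -1\n")
        neg = load_matrix(str(p))
        task = AlignmentTask(Sequence("q", "ARAR"), Sequence("s", "RARA"), neg, gaps)
        assert sw_score(task) == 0

    def test_empty_sequence_rejected(self, blosum62, gaps):
        from psse import SequenceError

        with pytest.raises(SequenceError):
            AlignmentTask(Sequence("q", ""), Sequence("s", "A"), blosum62, gaps)

    def test_gap_worth_opening_over_mismatch(self, blosum62, gaps):
        # WWWW vs WWAWW: skipping 'A' costs 12 but saves the W-vs-A mismatch run
        task = AlignmentTask(
            Sequence("q", "WWWW"), Sequence("s", "WWAWW"), blosum62, gaps
        )
        assert sw_score(task) == sw_score_exhaustive(
            Sequence("q", "WWWW"), Sequence("s", "WWAWW"), blosum62, gaps
        )

    def test_matches_exhaustive_oracle_on_random_pairs(self, blosum62, gaps):
        rng = np.random.default_rng(17)
        for _ in range(60):
            q, s = random_pair(rng)
            expected = sw_score_exhaustive(q, s, blosum62, gaps)
            assert sw_score(AlignmentTask(q, s, blosum62, gaps)) == expected

    def test_matches_biopython_aligner_on_medium_pairs(self, blosum62, gaps):
        """Independent cross-check against Bio.Align.PairwiseAligner."""
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -(gaps.open + gaps.extend)
        aligner.extend_gap_score = -gaps.extend
        rng = np.random.default_rng(23)
        for _ in range(15):
            q, s = random_pair(rng, max_len=80, alphabet="ACDEFGHIKLMNPQRSTVWY")
            ours = sw_score(AlignmentTask(q, s, blosum62, gaps))
            theirs = aligner.score(q.residues, s.residues)
            assert ours == int(theirs)

    def test_wavefront_order_identical_to_row_major(self, blosum62, gaps):
        rng = np.random.default_rng(5)
        for _ in range(40):
            q, s = random_pair(rng, max_len=12, alphabet="ACDEFGHIKL")
            task = AlignmentTask(q, s, blosum62, gaps)
            assert sw_score(task, order="row") == sw_score(task, order="wavefront")

    def test_symmetry_under_symmetric_matrix(self, blosum62, gaps):
        rng = np.random.default_rng(11)
        for _ in range(20):
            q, s = random_pair(rng, max_len=15)
            fwd = sw_score(AlignmentTask(q, s, blosum62, gaps))
            rev = sw_score(
                AlignmentTask(
                    Sequence("q", s.residues), Sequence("s", q.residues), blosum62, gaps
                )
            )
            assert fwd == rev

    @given(
        st.text(alphabet=REDUCED, min_size=1, max_size=10),
        st.text(alphabet=REDUCED, min_size=1, max_size=10),
        st.text(alphabet=REDUCED, min_size=1, max_size=3),
    )
    def test_appending_residues_never_decreases_score(self, q, s, extra):
        blosum62 = _BLOSUM
        gaps = GapPenalties()
        base = sw_score(AlignmentTask(Sequence("q", q), Sequence("s", s), blosum62, gaps))
        longer_s = sw_score(
            AlignmentTask(Sequence("q", q), Sequence("s", s + extra), blosum62, gaps)
        )
        longer_q = sw_score(
            AlignmentTask(Sequence("q", extra + q), Sequence("s", s), blosum62, gaps)
        )
        assert longer_s >= base
        assert longer_q >= base

    def test_profile_equivalence(self, blosum62, gaps):
        rng = np.random.default_rng(29)
        for _ in range(25):
            q, s = random_pair(rng, max_len=30, alphabet="ACDEFGHIKLMNPQRSTVWY")
            prof = build_local_profile(q, blosum62)
            via_matrix = sw_score(AlignmentTask(q, s, blosum62, gaps))
            via_profile = sw_score(AlignmentTask(q, s, prof, gaps))
            assert via_matrix == via_profile

    def test_profile_length_mismatch_rejected(self, blosum62, gaps):
        from psse import MatrixError

        prof = build_local_profile(Sequence("q", "ARND"), blosum62)
        with pytest.raises(MatrixError):
            AlignmentTask(Sequence("q", "ARNDA"), Sequence("s", "AR"), prof, gaps)


class TestSwScoreBatch:
    def test_singleton_batch_equals_single(self, blosum62, gaps):
        q = Sequence("q", "WARDN")
        s = Sequence("s", "WARD")
        assert sw_score_batch(q, [s], blosum62, gaps) == [
            sw_score(AlignmentTask(q, s, blosum62, gaps))
        ]

    def test_identical_subjects_identical_scores(self, blosum62, gaps):
        q = Sequence("q", "WARDN")
        subjects = [Sequence(f"s{i}", "DRAWN") for i in range(10)]
        scores = sw_score_batch(q, subjects, blosum62, gaps)
        assert len(set(scores)) == 1

    def test_batch_equals_loop_of_singles(self, blosum62, gaps):
        rng = np.random.default_rng(41)
        q = Sequence("q", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 40)))
        subjects = [
            Sequence(f"s{i}", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                                 rng.integers(5, 60))))
            for i in range(50)
        ]
        batch = sw_score_batch(q, subjects, blosum62, gaps)
        singles = [sw_score(AlignmentTask(q, s, blosum62, gaps)) for s in subjects]
        assert batch == singles

    def test_padding_never_affects_scores(self, blosum62, gaps):
        # mixed lengths force padding in the packed batch
        q = Sequence("q", "WARDN")
        subjects = [Sequence("a", "W"), Sequence("b", "WARDNWARDN")]
        batch = sw_score_batch(q, subjects, blosum62, gaps)
        singles = [sw_score(AlignmentTask(q, s, blosum62, gaps)) for s in subjects]
        assert batch == singles

    def test_empty_batch(self, blosum62, gaps):
        assert sw_score_batch(Sequence("q", "AR"), [], blosum62, gaps) == []
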