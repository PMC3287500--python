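"""Scale-up, sum-of-pairs (counting form vs brute force), matrix I/O."""

from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from meshalign.errors import InputError
from meshalign.oracles import oracle_sp
from meshalign.scoring import (
    GAP,
    ProfileColumn,
    ScoringScheme,
    SubstitutionMatrix,
    read_ncbi_matrix,
    scale_up,
    sp_pairs,
    sum_of_pair,
)

INDICATOR_TT = ScoringScheme(
    SubstitutionMatrix.from_pairs(
        "ACGT",
        {(a, b): (1 if (a, b) == ("T", "T") else 0)
         for a in "ACGT" for b in "ACGT" if a <= b},
    ),
    gap=-1,
)


class TestScaleUp:
    def test_shifts_by_most_negative_score(self):
        sch = ScoringScheme.constant("ACGT", match=3, mismatch=-4, gap=-2)
        scaled = scale_up(sch)
        assert scaled.beta == 4
        assert scaled.matrix.score("A", "A") == 7
        assert scaled.matrix.min_score() == 0
        assert scaled.gap == 2

    def test_non_negative_scheme_is_identity(self):
        sch = ScoringScheme.constant("ACGT", match=2, mismatch=1, gap=0)
        scaled = scale_up(sch)
        assert scaled.beta == 0
        assert scaled.matrix.scores == sch.matrix.scores

    def test_antilog_multiply_log_round_trip_equals_shift(self):
        """exp/log route: adding beta to log-odds == multiplying odds by a^beta."""
        import math

        scores = [-4, -1, 0, 2]
        beta = 4
        base = 2.0
        via_antilog = [
            round(math.log(base ** s * base ** beta, base)) for s in scores
        ]
        assert via_antilog == [s + beta for s in scores]


class TestSumOfPairs:
    def test_worked_example_pair_multiset(self):
        pairs, total = sp_pairs("ACT", "GTT")
        assert total == 15
        assert pairs == Counter(
            {
                ("A", "C"): 1,
                ("A", "T"): 3,
                ("A", "G"): 1,
                ("C", "T"): 3,
                ("C", "G"): 1,
                ("G", "T"): 3,
                ("T", "T"): 3,
            }
        )

    def test_worked_example_indicator_score(self):
        f = ProfileColumn.from_residues("ACT")
        g = ProfileColumn.from_residues("GTT")
        assert sum_of_pair(f, g, INDICATOR_TT) == 3
        assert oracle_sp("ACT", "GTT", INDICATOR_TT) == 3

    def test_single_residues_reduce_to_substitution_score(self, dna_scheme):
        f = ProfileColumn.from_residues("A")
        g = ProfileColumn.from_residues("C")
        assert sum_of_pair(f, g, dna_scheme) == dna_scheme.s("A", "C")

    def test_counting_form_equals_brute_force_on_random_columns(self, rng):
        symbols = list("ACGT" + GAP)
        for _ in range(500):
            scores = {
                (a, b): int(rng.integers(-5, 6))
                for i, a in enumerate("ACGT")
                for b in "ACGT"[i:]
            }
            sch = ScoringScheme(
                SubstitutionMatrix.from_pairs("ACGT", scores),
                gap=int(rng.integers(-4, 1)),
                gap_gap=int(rng.integers(-2, 3)),
            )
            nf = int(rng.integers(1, 11))
            ng = int(rng.integers(1, 11))
            f = [symbols[int(rng.integers(5))] for _ in range(nf)]
            g = [symbols[int(rng.integers(5))] for _ in range(ng)]
            expected = oracle_sp(f, g, sch)
            got = sum_of_pair(
                ProfileColumn.from_residues(f), ProfileColumn.from_residues(g), sch
            )
            assert got == expected

    @given(st.text(alphabet="ACGT-", min_size=1, max_size=8),
           st.text(alphabet="ACGT-", min_size=1, max_size=8))
    @settings(max_examples=100, derandomize=True)
    def test_pair_count_is_always_choose_two(self, f, g):
        _, total = sp_pairs(f, g)
        n = len(f) + len(g)
        assert total == n * (n - 1) // 2


class TestNCBIMatrixReader:
    MATRIX_TEXT = """\
# toy DNA matrix
   A  C  G  T
A  5 -4 -4 -4
C -4  5 -4 -4
G -4 -4  5 -4
T -4 -4 -4  5
"""

    def test_reads_symmetric_matrix(self, tmp_path):
        p = tmp_path / "toy.mat"
        p.write_text(self.MATRIX_TEXT)
        mat = read_ncbi_matrix(p)
        assert mat.score("A", "A") == 5
        assert mat.score("A", "C") == -4
        assert mat.is_symmetric()

    def test_asymmetric_matrix_rejected(self, tmp_path):
        bad = self.MATRIX_TEXT.replace("G -4 -4  5 -4", "G -4 -1  5 -4")
        p = tmp_path / "bad.mat"
        p.write_text(bad)
        with pytest.raises(InputError):
            read_ncbi_matrix(p)

    def test_reports_line_number_for_garbage(self, tmp_path):
        p = tmp_path / "bad.mat"
        p.write_text("   A  C\nA  1\n")
        with pytest.raises(InputError, match="line 2"):
            read_ncbi_matrix(p)
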