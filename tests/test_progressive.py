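"""Group alignment and the end-to-end progressive pipeline."""

import numpy as np
import pytest

from meshalign.dpmesh import align
from meshalign.errors import InputError
from meshalign.oracles import oracle_progressive_msa
from meshalign.progressive import (
    AlignedGroup,
    group_align,
    pairwise_all,
    progressive_msa,
)
from meshalign.scoring import GAP, ScoringScheme, scale_up
from meshalign.synth import synth_family

from conftest import random_dna

SCALED = scale_up(ScoringScheme.constant("ACGT", 1, 0, -1))


class TestPairwiseAll:
    def test_identical_pair_scores_maximally(self, dna_scheme):
        S = pairwise_all(["ACGT", "ACGT"], dna_scheme)
        assert S[0, 1] == S[0, 0] == 4 * 2

    def test_symmetry_on_random_inputs(self, rng, dna_scheme):
        seqs = [random_dna(rng, 2, 8) for _ in range(4)]
        S = pairwise_all(seqs, dna_scheme)
        assert (S == S.T).all()

    def test_matches_per_pair_alignment(self, dna_scheme):
        seqs = ["ACGT", "AGT", "CCGT"]
        S = pairwise_all(seqs, dna_scheme)
        for i in range(3):
            for j in range(3):
                res, _ = align(seqs[i], seqs[j], dna_scheme, "nw")
                assert S[i, j] == res.score


class TestGroupAlign:
    def test_singleton_groups_reduce_to_pairwise_dp(self, rng):
        """SP of singleton columns is the substitution score, so group DP
        over two single-sequence groups must equal pairwise DP exactly."""
        for _ in range(25):
            x = random_dna(rng, 1, 8)
            y = random_dna(rng, 1, 8)
            merged, score = group_align(
                AlignedGroup.from_sequence("x", x),
                AlignedGroup.from_sequence("y", y),
                SCALED,
            )
            res, _ = align(x, y, SCALED, "nw")
            assert score == res.score
            assert merged.rows == [res.aligned_x, res.aligned_y]

    def test_aligning_gap_free_group_with_itself_adds_no_gaps(self):
        g = AlignedGroup(["a", "b"], ["ACGGT", "ACCGT"])
        merged, _ = group_align(g, g, SCALED)
        assert merged.rows == g.rows + g.rows

    def test_column_path_optimality_by_enumeration(self, rng):
        """Group DP equals brute force over all monotone column paths."""

        def brute(A, B, scheme):
            from meshalign.progressive import _grid_scores

            diag, gx, gy = _grid_scores(A, B, scheme)
            best = {}

            def rec(i, j):
                if (i, j) in best:
                    return best[(i, j)]
                if i == 0 and j == 0:
                    return 0
                cands = []
                if i > 0 and j > 0:
                    cands.append(rec(i - 1, j - 1) + diag[i - 1, j - 1])
                if i > 0:
                    cands.append(rec(i - 1, j) + (gx[i - 1] if j > 0 else 0))
                if j > 0:
                    cands.append(rec(i, j - 1) + (gy[j - 1] if i > 0 else 0))
                best[(i, j)] = max(cands)
                return best[(i, j)]

            return rec(A.length, B.length)

        for _ in range(10):
            rows_a = [random_dna(rng, 5, 5), random_dna(rng, 5, 5)]
            rows_b = [random_dna(rng, 6, 6), random_dna(rng, 6, 6)]
            A = AlignedGroup(["a1", "a2"], rows_a)
            B = AlignedGroup(["b1", "b2"], rows_b)
            _, score = group_align(A, B, SCALED)
            assert score == brute(A, B, SCALED)

    def test_engines_agree_on_groups(self, rng):
        A = AlignedGroup(["a1", "a2"], ["ACG-T", "AC-GT"])
        B = AlignedGroup(["b1"], ["AGGT"])
        m_ref, s_ref = group_align(A, B, SCALED, engine="reference")
        m_mesh, s_mesh = group_align(A, B, SCALED, engine="mesh")
        assert m_ref.rows == m_mesh.rows and s_ref == s_mesh


class TestProgressiveMSA:
    def test_two_sequences_reduce_to_pairwise(self, rng):
        x, y = random_dna(rng, 4, 8), random_dna(rng, 4, 8)
        sch = ScoringScheme.constant("ACGT", 1, 0, -1)
        result = progressive_msa([x, y], sch)
        res, _ = align(x, y, scale_up(sch), "nw")
        assert result.alignment.rows == [res.aligned_x, res.aligned_y]

    def test_identical_pair_merges_first(self):
        """The zero-distance pair joins first (4 taxa: at 3 every pair ties)."""
        seqs = ["ACGTACGT", "TTTTCCCC", "ACGTACGT", "GGGGAAAA"]
        sch = ScoringScheme.constant("ACGT", 1, 0, -1)
        result = progressive_msa(seqs, sch)
        first_merge = result.tree.merge_order[0]
        joined = {first_merge[0].label, first_merge[1].label}
        assert joined == {"seq0", "seq2"}

    def test_degapping_recovers_inputs(self, rng):
        for seed in (1, 2, 3):
            seqs, _ = synth_family(5, 10, 0.25, 0.1, seed=seed)
            result = progressive_msa(seqs, ScoringScheme.constant("ACGT", 1, 0, -1))
            assert result.alignment.degapped() == seqs
            assert len({len(r) for r in result.alignment.rows}) == 1

    def test_mesh_and_reference_engines_identical(self):
        seqs, _ = synth_family(4, 8, 0.2, 0.1, seed=5)
        sch = ScoringScheme.constant("ACGT", 1, 0, -1)
        r_ref = progressive_msa(seqs, sch, engine="reference")
        r_mesh = progressive_msa(seqs, sch, engine="mesh")
        assert r_ref.alignment.rows == r_mesh.alignment.rows
        assert r_ref.merge_scores == r_mesh.merge_scores

    def test_matches_independent_sequential_reference(self):
        for seed in (7, 8):
            seqs, _ = synth_family(5, 9, 0.2, 0.08, seed=seed)
            sch = ScoringScheme.constant("ACGT", 1, 0, -1)
            result = progressive_msa(seqs, sch, engine="reference")
            _, oracle_rows = oracle_progressive_msa(seqs, sch)
            assert result.alignment.rows == oracle_rows

    def test_merge_scores_rescore_from_columns(self):
        """Each merge score is reproducible from the merged group's columns."""
        seqs, _ = synth_family(4, 8, 0.2, 0.05, seed=11)
        sch = ScoringScheme.constant("ACGT", 1, 0, -1)
        result = progressive_msa(seqs, sch)
        work = result.scheme_used
        final_label, final_score = result.merge_scores[-1]
        # rebuild the last merge from the tree and re-run its DP
        left, right, _ = result.tree.merge_order[-1]

        def group_for(node):
            labels = [leaf.label for leaf in node.leaves()]
            rows = {
                sid: row
                for sid, row in zip(result.alignment.ids, result.alignment.rows)
            }
            # degap columns that are all-gap within this subgroup
            sub = [rows[lab] for lab in labels]
            keep = [
                j for j in range(len(sub[0]))
                if any(r[j] != GAP for r in sub)
            ]
            return AlignedGroup(labels, ["".join(r[j] for j in keep) for r in sub])

        _, score = group_align(group_for(left), group_for(right), work)
        assert score == final_score

    def test_single_sequence_rejected(self, dna_scheme):
        with pytest.raises(InputError):
            progressive_msa(["ACGT"], dna_scheme)

    def test_resource_log_recomputes_from_closed_forms(self):
        from meshalign import resources

        seqs, _ = synth_family(4, 8, 0.2, 0.05, seed=11)
        sch = ScoringScheme.constant("ACGT", 1, 0, -1)
        result = progressive_msa(seqs, sch)
        log = result.resource_log
        n, m, k = log["n"], log["m"], log["k"]
        assert log["nj_units"] == m ** 3
        assert log["sum_of_pair_units"] == m * n * n
        assert log["backtracking_units"] == n ** 3
        expected_dp = (
            resources.dp_mesh_constant(n)
            if log["scheme_constant"]
            else resources.dp_mesh_general(n, k)
        )
        assert log["dp_mesh_units"] == expected_dp
        assert log["msa_units"] == m * expected_dp
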