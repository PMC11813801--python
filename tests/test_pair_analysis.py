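import math

import numpy as np
import pytest

from motifpairs.io_formats import MotifMatrixFile
from motifpairs.motif_models import matrix_from_consensus
from motifpairs.pair_analysis import (
    MotifCollection,
    analyze_all_pairs,
    analyze_collection_topk,
    analyze_one_vs_collection,
    analyze_pair,
    pwm_similarity,
)
from motifpairs.prcurve import AnalysisConfig
from oracles import oracle_similarity

CFG = AnalysisConfig(errmax=0.002)


class TestAnalyzePair:
    def test_self_pair_has_unit_rauc_and_is_flagged_redundant(
        self, calibrated, exclusive_data
    ):
        data, _ = exclusive_data
        res = analyze_pair(calibrated["A"], calibrated["A"], data, CFG)
        assert res.pauprc_joint == res.pauprc_a
        assert res.rauc == 1.0
        assert res.similarity_score == pytest.approx(1.0)
        assert res.similarity_flag == "redundant"

    def test_exclusive_pair_beats_both_singles(self, calibrated, exclusive_data):
        data, _ = exclusive_data
        res = analyze_pair(calibrated["A"], calibrated["B"], data, CFG)
        assert res.pauprc_joint > max(res.pauprc_a, res.pauprc_b)
        assert res.rauc > 1.0
        assert res.similarity_flag == "distinct"

    def test_deterministic(self, calibrated, exclusive_data):
        data, _ = exclusive_data
        r1 = analyze_pair(calibrated["A"], calibrated["B"], data, CFG)
        r2 = analyze_pair(calibrated["A"], calibrated["B"], data, CFG)
        assert r1 == r2


class TestAllPairs:
    def test_k_motifs_give_k_choose_2_pairs(self, calibrated, exclusive_data):
        data, _ = exclusive_data
        coll = MotifCollection(list(calibrated.values()))
        matrix = analyze_all_pairs(coll, data, CFG)
        assert len(matrix.results) == 3  # K=3 -> 3 pairs
        assert matrix.rauc.shape == (3, 3)

    def test_matrix_is_symmetric_with_unit_diagonal(
        self, calibrated, exclusive_data
    ):
        data, _ = exclusive_data
        matrix = analyze_all_pairs(MotifCollection(list(calibrated.values())), data, CFG)
        r = matrix.rauc.to_numpy()
        mask = ~np.isnan(r)
        assert np.array_equal(r[mask], r.T[mask])
        for name in matrix.names:
            if matrix.pauprc_single[name] > 0:
                assert matrix.rauc.loc[name, name] == 1.0

    def test_restriction_to_a_subset_is_consistent(self, calibrated, exclusive_data):
        data, _ = exclusive_data
        full = analyze_all_pairs(MotifCollection(list(calibrated.values())), data, CFG)
        sub = analyze_all_pairs(
            MotifCollection([calibrated["A"], calibrated["B"]]), data, CFG
        )
        assert full.rauc.loc["A", "B"] == sub.rauc.loc["A", "B"]
        assert full.pauprc_single["A"] == sub.pauprc_single["A"]

    def test_needs_at_least_two_motifs(self, calibrated, exclusive_data):
        data, _ = exclusive_data
        with pytest.raises(ValueError):
            analyze_all_pairs(MotifCollection([calibrated["A"]]), data, CFG)


class TestOneVsCollection:
    def test_ranking_is_a_permutation_sorted_by_rauc(
        self, calibrated, exclusive_data
    ):
        data, _ = exclusive_data
        coll = MotifCollection(list(calibrated.values()))
        ranked = analyze_one_vs_collection(calibrated["A"], coll, data, CFG)
        assert sorted(r.motif_b for r in ranked) == sorted(coll.names)
        raucs = [r.rauc for r in ranked if not math.isnan(r.rauc)]
        assert raucs == sorted(raucs, reverse=True)

    def test_query_against_itself_scores_unit_rauc(self, calibrated, exclusive_data):
        data, _ = exclusive_data
        coll = MotifCollection(list(calibrated.values()))
        ranked = analyze_one_vs_collection(calibrated["A"], coll, data, CFG)
        self_pair = next(r for r in ranked if r.motif_b == "A")
        assert self_pair.rauc == 1.0

    def test_collection_of_one(self, calibrated, exclusive_data):
        data, _ = exclusive_data
        ranked = analyze_one_vs_collection(
            calibrated["A"], MotifCollection([calibrated["B"]]), data, CFG
        )
        assert len(ranked) == 1


class TestTopK:
    def test_selection_matches_exhaustive_sort(self, calibrated, exclusive_data):
        data, _ = exclusive_data
        coll = MotifCollection(list(calibrated.values()))
        full = analyze_all_pairs(coll, data, CFG)
        expected = sorted(
            coll.names, key=lambda n: (-full.pauprc_single[n], n)
        )[:2]
        top = analyze_collection_topk(coll, 2, data, CFG)
        assert sorted(top.names) == sorted(expected)
        assert len(top.results) == 1  # k=2 -> exactly one pair

    def test_k_equal_to_collection_size_is_all_pairs(
        self, calibrated, exclusive_data
    ):
        data, _ = exclusive_data
        coll = MotifCollection(list(calibrated.values()))
        full = analyze_all_pairs(coll, data, CFG)
        top = analyze_collection_topk(coll, len(coll), data, CFG)
        assert top.rauc.sort_index().sort_index(axis=1).equals(
            full.rauc.sort_index().sort_index(axis=1)
        )

    def test_k_below_two_is_an_error(self, calibrated, exclusive_data):
        data, _ = exclusive_data
        coll = MotifCollection(list(calibrated.values()))
        with pytest.raises(ValueError):
            analyze_collection_topk(coll, 1, data, CFG)


class TestPwmSimilarity:
    def test_identity_is_perfectly_similar_and_redundant(self):
        a = matrix_from_consensus("ACGTACGT")
        score, flag = pwm_similarity(a, a)
        assert score == pytest.approx(1.0)
        assert flag == "redundant"

    def test_reverse_complement_found_by_orientation_search(self):
        a = MotifMatrixFile(
            "a", np.array([[8, 1, 1, 1], [1, 8, 1, 1], [1, 1, 8, 1], [1, 1, 1, 8], [8, 1, 1, 1]], float)
        )
        score, flag = pwm_similarity(a, a.reverse_complement())
        assert score == pytest.approx(1.0)
        assert flag == "redundant"

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        a = MotifMatrixFile("a", rng.integers(1, 20, size=(6, 4)).astype(float))
        b = MotifMatrixFile("b", rng.integers(1, 20, size=(9, 4)).astype(float))
        assert pwm_similarity(a, b)[0] == pytest.approx(pwm_similarity(b, a)[0])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_placement_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = MotifMatrixFile("a", rng.integers(1, 20, size=(rng.integers(4, 9), 4)).astype(float))
        b = MotifMatrixFile("b", rng.integers(1, 20, size=(rng.integers(4, 9), 4)).astype(float))
        got, _ = pwm_similarity(a, b)
        want = oracle_similarity(a.counts.tolist(), b.counts.tolist())
        assert got == pytest.approx(want, abs=1e-12)

    def test_dissimilar_sharp_motifs_are_distinct(self):
        a = matrix_from_consensus("AAAAAAAA")
        b = matrix_from_consensus("ACGCGCGT")
        score, flag = pwm_similarity(a, b)
        assert flag == "distinct"
        assert score < 0.9
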