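import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motifpairs.calibration import (
    ABOVE_CEILING,
    CalibrationConfig,
    ErrTable,
    base_composition,
    compute_err_table,
    err_table_from_scores,
    read_err_table,
    thresholds_under,
    write_err_table,
)
from motifpairs.io_formats import MotifMatrixFile, SequenceRecord, SequenceSet
from motifpairs.motif_models import PositionWeightMatrix, build_pwm, matrix_from_consensus
from motifpairs.synthetic_data import gen_background
from oracles import oracle_err_table


def pwm_of(consensus):
    return build_pwm(matrix_from_consensus(consensus))


class TestComputeErrTable:
    def test_two_short_promoters_count_both_strands(self):
        """2 promoters of 6 bp, motif length 4: 2*2*(6-4+1) = 12 positions."""
        seqs = SequenceSet(
            [SequenceRecord("p1", "ACGTAC"), SequenceRecord("p2", "GGTACG")],
            label="promoter",
        )
        pwm = pwm_of("ACGT")
        table = compute_err_table(
            pwm, seqs, CalibrationConfig(err_ceiling=1.0, errmax=1.0)
        )
        assert table.n_positions == 12
        entries, n = oracle_err_table(pwm, seqs, err_ceiling=1.0)
        assert n == 12
        np.testing.assert_array_equal(table.thresholds, [t for t, _ in entries])
        np.testing.assert_array_equal(table.errs, [e for _, e in entries])
        # survival fractions are multiples of 1/12: a threshold passed by
        # exactly 3 of the 12 windows has err 0.25
        counts = np.round(table.errs * 12).astype(int)
        np.testing.assert_allclose(counts / 12.0, table.errs)
        if 3 in counts:
            assert table.errs[list(counts).index(3)] == 0.25

    def test_threshold_at_global_minimum_has_err_one(self):
        seqs = SequenceSet([SequenceRecord("p1", "ACGTACGTAA")], label="promoter")
        table = compute_err_table(
            pwm_of("ACGT"), seqs, CalibrationConfig(err_ceiling=1.0, errmax=1.0)
        )
        assert table.errs[-1] == 1.0

    def test_ns_excluded_from_numerator_and_denominator(self):
        seqs = SequenceSet([SequenceRecord("p1", "ACGTNACG")], label="promoter")
        pwm = pwm_of("ACG")
        table = compute_err_table(
            pwm, seqs, CalibrationConfig(err_ceiling=1.0, errmax=1.0)
        )
        entries, n = oracle_err_table(pwm, seqs, err_ceiling=1.0)
        assert table.n_positions == n < 2 * (8 - 3 + 1)

    def test_constant_scorer_truncates_to_empty_with_warning(self, caplog):
        seqs = SequenceSet([SequenceRecord("p1", "ACGTACGT")], label="promoter")
        flat = PositionWeightMatrix("flat", np.zeros((4, 4)))
        with caplog.at_level("WARNING"):
            table = compute_err_table(flat, seqs, CalibrationConfig())
        assert len(table) == 0
        assert "no usable thresholds" in caplog.text
        assert table.score_to_err(0.0) == ABOVE_CEILING

    def test_all_n_calibration_set_is_an_error(self):
        seqs = SequenceSet([SequenceRecord("p1", "NNNNNNNN")], label="promoter")
        with pytest.raises(ValueError, match="calibration set too small"):
            compute_err_table(pwm_of("ACGT"), seqs, CalibrationConfig())

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        seqs = gen_background(
            n=int(rng.integers(2, 5)),
            length=int(rng.integers(20, 60)),
            gc=float(rng.uniform(0.3, 0.7)),
            seed=seed,
        )
        counts = rng.integers(0, 9, size=(int(rng.integers(3, 6)), 4)) + 1
        pwm = build_pwm(MotifMatrixFile("m", counts.astype(float)))
        table = compute_err_table(
            pwm, seqs, CalibrationConfig(err_ceiling=1.0, errmax=1.0)
        )
        entries, n = oracle_err_table(pwm, seqs, err_ceiling=1.0)
        assert table.n_positions == n
        np.testing.assert_array_equal(table.thresholds, [t for t, _ in entries])
        np.testing.assert_array_equal(table.errs, [e for _, e in entries])

    def test_quantile_grid_keeps_endpoints(self):
        seqs = gen_background(4, 80, 0.5, seed=3)
        full = compute_err_table(
            pwm_of("ACGT"), seqs, CalibrationConfig(err_ceiling=1.0, errmax=1.0)
        )
        grid = compute_err_table(
            pwm_of("ACGT"),
            seqs,
            CalibrationConfig(err_ceiling=1.0, errmax=1.0, max_thresholds=5),
        )
        assert len(grid) <= 5
        assert grid.thresholds[0] == full.thresholds[0]
        assert grid.thresholds[-1] == full.thresholds[-1]


FIXED_TABLE = ErrTable(
    thresholds=np.array([4.0, 3.0, 2.0, 1.0]),
    errs=np.array([0.0005, 0.001, 0.002, 0.005]),
    n_positions=2000,
    model_name="toy",
)


class TestScoreToErr:
    def test_score_at_top_threshold_gets_smallest_err(self):
        assert FIXED_TABLE.score_to_err(4.0) == 0.0005
        assert FIXED_TABLE.score_to_err(99.0) == 0.0005

    def test_score_between_thresholds_steps_down_to_lower_one(self):
        # t1=3 > s=2.5 >= t2=2 -> err(t2)
        assert FIXED_TABLE.score_to_err(2.5) == 0.002

    def test_score_below_all_thresholds_is_above_ceiling(self):
        assert FIXED_TABLE.score_to_err(0.5) == ABOVE_CEILING
        assert FIXED_TABLE.score_to_err(float("nan")) == ABOVE_CEILING

    def test_vectorized_lookup(self):
        out = FIXED_TABLE.score_to_err(np.array([4.0, 2.5, 0.5]))
        np.testing.assert_array_equal(out, [0.0005, 0.002, np.inf])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=20, unique=True))
    def test_monotone_nonincreasing_in_score(self, scores):
        table = err_table_from_scores(np.array(scores), err_ceiling=1.0)
        probe = np.sort(np.array(scores + [-11.0, 11.0]))
        errs = table.score_to_err(probe)
        assert np.all(np.diff(errs) <= 0)


class TestThresholdsUnder:
    def test_strict_inequality_excludes_ties(self):
        np.testing.assert_array_equal(
            thresholds_under(FIXED_TABLE, 0.002), [0.0005, 0.001]
        )

    def test_errmax_one_keeps_everything(self):
        np.testing.assert_array_equal(
            thresholds_under(FIXED_TABLE, 1.0), FIXED_TABLE.errs
        )

    def test_no_threshold_under_errmax_gives_empty(self):
        assert thresholds_under(FIXED_TABLE, 0.0001).size == 0

    def test_bad_errmax(self):
        with pytest.raises(ValueError):
            thresholds_under(FIXED_TABLE, 0.0)


class TestConfigAndIo:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"errmax": 0.0},
            {"errmax": 0.05, "err_ceiling": 0.02},
            {"err_ceiling": 1.5},
            {"max_thresholds": 0},
        ],
    )
    def test_invalid_config(self, kwargs):
        with pytest.raises(ValueError):
            CalibrationConfig(**kwargs)

    def test_err_table_roundtrip(self, tmp_path):
        path = tmp_path / "table.tsv"
        write_err_table(FIXED_TABLE, path)
        back = read_err_table(path)
        np.testing.assert_array_equal(back.thresholds, FIXED_TABLE.thresholds)
        np.testing.assert_array_equal(back.errs, FIXED_TABLE.errs)
        assert back.n_positions == 2000
        assert back.model_name == "toy"

    def test_table_rejects_nonmonotone_entries(self):
        with pytest.raises(ValueError):
            ErrTable(
                thresholds=np.array([1.0, 2.0]),
                errs=np.array([0.1, 0.2]),
                n_positions=10,
            )


def test_base_composition_ignores_ns_and_falls_back_to_uniform():
    seqs = SequenceSet([SequenceRecord("a", "AACGN")])
    np.testing.assert_allclose(base_composition(seqs), [0.5, 0.25, 0.25, 0.0])
    all_n = SequenceSet([SequenceRecord("a", "NNN")])
    np.testing.assert_allclose(base_composition(all_n), [0.25] * 4)
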