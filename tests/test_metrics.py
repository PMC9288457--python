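"""Closed-form metric layer: RMSE variants, B-Score, inverse, reporting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bscore import (
    BPDataset,
    b1_rmse,
    b2_rmse,
    b_score,
    b_score_value,
    coequal_t_rmse,
    format_b_score,
    rmse,
    t_rmse,
    validate_dataset,
)
from bscore.metrics import BELOW_ZERO_TEXT

from conftest import make_frame

positive_rmse = st.floats(min_value=0.5, max_value=200.0, allow_nan=False)


# ----------------------------------------------------------------------
# rmse / t_rmse
# ----------------------------------------------------------------------
class TestRmse:
    def test_constant_four_mmhg_error(self):
        # uniform 4 mmHg error: MAE and RMSE agree at 4.0
        refs = np.full(10, 120.0)
        preds = refs + 4.0
        assert rmse(preds, refs) == pytest.approx(4.0)
        assert np.mean(np.abs(preds - refs)) == pytest.approx(4.0)

    def test_alternating_zero_eight_error(self):
        # same MAE (4.0) but inconsistent errors push the RMSE to 5.66
        refs = np.full(10, 120.0)
        preds = refs + np.tile([0.0, 8.0], 5)
        assert np.mean(np.abs(preds - refs)) == pytest.approx(4.0)
        assert rmse(preds, refs) == pytest.approx(5.6569, abs=1e-4)
        assert round(rmse(preds, refs), 2) == 5.66

    def test_identity_and_constant_offset(self):
        refs = np.array([100.0, 120.0, 140.0])
        assert rmse(refs, refs) == 0.0
        for c in (-5.0, 3.0):
            assert rmse(refs + c, refs) == pytest.approx(abs(c))

    @pytest.mark.parametrize(
        "preds, refs",
        [([1.0, 2.0], [1.0]), ([], []), ([np.nan, 1.0], [0.0, 1.0])],
        ids=["length-mismatch", "empty", "non-finite"],
    )
    def test_invalid_inputs_rejected(self, preds, refs):
        with pytest.raises(ValueError):
            rmse(preds, refs)

    @given(
        errors=st.lists(st.floats(min_value=-50, max_value=50), min_size=1, max_size=30),
    )
    @settings(max_examples=200, derandomize=True)
    def test_rmse_dominates_mae(self, errors):
        # Jensen: RMSE >= MAE, equality iff all |errors| equal
        refs = np.full(len(errors), 100.0)
        preds = refs + np.array(errors)
        r = rmse(preds, refs)
        mae = float(np.mean(np.abs(errors)))
        assert r >= mae - 1e-12
        if len(set(round(abs(e), 9) for e in errors)) > 1:
            assert r >= mae

    def test_t_rmse_reads_selected_channel(self, toy_dataset):
        preds = toy_dataset.values + 3.0
        assert t_rmse(toy_dataset, preds) == pytest.approx(3.0)
        dia = toy_dataset.with_channel("diastolic")
        assert t_rmse(dia, dia.values) == 0.0

    def test_t_rmse_passthrough_error_vector(self, toy_dataset):
        # a fixed device-error vector with RMSE 9.64 reproduces that T-RMSE
        rng = np.random.default_rng(3)
        errors = rng.normal(0, 1, 9)
        errors *= 9.64 / rmse(errors + toy_dataset.values, toy_dataset.values)
        assert t_rmse(toy_dataset, toy_dataset.values + errors) == pytest.approx(9.64)


# ----------------------------------------------------------------------
# base performances from data
# ----------------------------------------------------------------------
class TestBasePerformances:
    def test_b1_hand_example(self):
        ds = BPDataset(make_frame({"A": [100], "B": [110], "C": [120]}))
        assert b1_rmse(ds) == pytest.approx(np.sqrt(200.0 / 3.0), abs=1e-4)
        assert b1_rmse(ds) == pytest.approx(8.1650, abs=1e-4)

    def test_b1_constant_dataset_is_zero(self):
        ds = BPDataset(make_frame({"A": [120, 120], "B": [120]}))
        assert b1_rmse(ds) == 0.0

    @given(st.lists(st.floats(min_value=50, max_value=250), min_size=2, max_size=40))
    @settings(max_examples=150, derandomize=True)
    def test_b1_equals_scaled_sample_sd(self, values):
        # population SD identity: b1 = sqrt((n-1)/n) * sample SD
        ds = BPDataset(make_frame({"A": values}))
        n = len(values)
        expected = np.std(values, ddof=1) * np.sqrt((n - 1) / n)
        assert b1_rmse(ds) == pytest.approx(expected, abs=1e-9)

    def test_b2_single_subject(self):
        ds = BPDataset(make_frame({"A": [120, 124, 128]}))
        assert b2_rmse(ds) == pytest.approx(np.sqrt(80.0 / 3.0), abs=1e-4)
        assert b2_rmse(ds) == pytest.approx(5.1640, abs=1e-4)

    def test_b2_two_subjects(self):
        ds = BPDataset(make_frame({"A": [120, 124, 128], "B": [80, 80, 80]}))
        assert b2_rmse(ds) == pytest.approx(np.sqrt(80.0 / 6.0), abs=1e-4)
        assert b2_rmse(ds) == pytest.approx(3.6515, abs=1e-4)

    def test_b2_constant_subjects_zero(self):
        ds = BPDataset(make_frame({"A": [120, 120, 120], "B": [90, 90]}))
        assert b2_rmse(ds) == 0.0

    def test_b2_uses_time_order_not_row_order(self):
        frame = make_frame({"A": [124, 128, 120]})
        frame["time"] = [2.0, 1.0, 0.0]  # calibration is the value at t=0
        ds = BPDataset(frame)
        assert b2_rmse(ds) == pytest.approx(np.sqrt(80.0 / 3.0), abs=1e-4)


# ----------------------------------------------------------------------
# B-Score and inverse
# ----------------------------------------------------------------------
class TestBScore:
    def test_published_systolic_value(self):
        result = b_score(32.25, 28.71, 26.83, 9.64)
        assert result.value == pytest.approx(0.9437, abs=5e-4)
        # third decimal: closed form gives 0.94375 (printed as 0.943)
        assert result.value == pytest.approx(0.943, abs=1e-3)
        assert result.formatted == "0.94"

    def test_published_diastolic_below_zero(self):
        result = b_score(8.98, 7.86, 7.95, 10.35)
        assert result.below_zero and result.value is None
        assert result.formatted == BELOW_ZERO_TEXT

    def test_equality_boundary_triggers_reporting_rule(self):
        assert b_score(10, 10, 10, 10).below_zero
        assert b_score(10, 10, 10, 10 - 1e-9).value == pytest.approx(0.0, abs=1e-8)

    def test_scale_invariance_published_tuple(self):
        a = b_score(32.25, 28.71, 26.83, 9.64).value
        b = b_score(2 * 32.25, 2 * 28.71, 2 * 26.83, 2 * 9.64).value
        assert a == pytest.approx(b, abs=1e-12)

    @pytest.mark.parametrize("bad", [(0, 10, 10, 5), (10, 10, 10, 0)])
    def test_zero_inputs_domain_error(self, bad):
        with pytest.raises(ZeroDivisionError):
            b_score(*bad)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            b_score(-1, 10, 10, 5)

    @given(b1=positive_rmse, b2=positive_rmse, m=positive_rmse, t=positive_rmse)
    @settings(max_examples=1000, derandomize=True)
    def test_matches_printed_formula(self, b1, b2, m, t):
        # stable log form == literal log10(sqrt((b1*m/t^2)*(b2*m/t^2)))
        literal = np.log10(np.sqrt((b1 * m / t**2) * (b2 * m / t**2)))
        assert b_score_value(b1, b2, m, t) == pytest.approx(literal, abs=1e-12)

    @given(b1=positive_rmse, b2=positive_rmse, m=positive_rmse, t=positive_rmse, c=st.floats(min_value=0.01, max_value=100))
    @settings(max_examples=300, derandomize=True)
    def test_scale_invariance(self, b1, b2, m, t, c):
        assert b_score_value(c * b1, c * b2, c * m, c * t) == pytest.approx(
            b_score_value(b1, b2, m, t), abs=1e-9
        )

    def test_strict_monotonicity_on_grids(self):
        grid = np.linspace(5, 40, 12)
        base = (20.0, 18.0, 15.0, 5.0)
        scores_t = [b_score_value(base[0], base[1], base[2], t) for t in grid]
        assert all(a > b for a, b in zip(scores_t, scores_t[1:]))
        for pos in range(3):  # increasing in each base performance
            scores = []
            for v in grid:
                args = list(base)
                args[pos] = v
                scores.append(b_score_value(*args))
            assert all(a < b for a, b in zip(scores, scores[1:]))

    @given(b1=positive_rmse, b2=positive_rmse, m=positive_rmse, frac=st.floats(min_value=0.05, max_value=0.95))
    @settings(max_examples=1000, derandomize=True)
    def test_inverse_round_trip(self, b1, b2, m, frac):
        t = frac * min(b1, b2, m)  # keep the score defined
        score = b_score(b1, b2, m, t).value
        back = coequal_t_rmse(b1, b2, m, score)
        assert back.attainable
        assert back.t == pytest.approx(t, rel=1e-9)

    def test_coequal_all_equal_fixed_point(self):
        result = coequal_t_rmse(10, 10, 10, 0.0)
        assert result.t == pytest.approx(10.0, abs=1e-12)
        assert not result.attainable  # at equality the score is undefined

    def test_coequal_published_mimic_value(self):
        target = b_score(32.25, 28.71, 26.83, 9.64).value
        result = coequal_t_rmse(22.96, 21.97, 19.07, target)
        assert result.t == pytest.approx(6.98, abs=0.02)
        assert result.attainable

    def test_unattainable_target_flagged(self):
        # a huge target score would need t below any sane error; still flagged
        # when t >= min(b1,b2,m), i.e. the target is reachable outright
        result = coequal_t_rmse(8.98, 7.86, 7.95, -1.0)
        assert result.t >= min(8.98, 7.86, 7.95)
        assert not result.attainable


# ----------------------------------------------------------------------
# reporting and validity rules
# ----------------------------------------------------------------------
class TestReporting:
    @pytest.mark.parametrize(
        "value, text",
        [(0.9437, "0.94"), (1.0, "1.00"), (0.945, "0.95"), (-0.004, "-0.00"), (2.675, "2.68")],
    )
    def test_two_decimal_half_up(self, value, text):
        assert format_b_score(value) == text

    def test_below_zero_literal(self):
        assert format_b_score(b_score(8.98, 7.86, 7.95, 10.35)) == BELOW_ZERO_TEXT

    def test_two_subjects_hard_failure(self):
        ds = BPDataset(make_frame({"A": [1] * 50, "B": [2] * 50}, ))
        report = validate_dataset(ds)
        assert not report.valid

    def test_small_valid_dataset_warns(self, toy_dataset):
        report = validate_dataset(toy_dataset)
        assert report.valid
        assert any("100" in w for w in report.warnings)

    def test_hundred_measurements_no_warning(self):
        ds = BPDataset(make_frame({f"S{i}": list(range(100, 110)) for i in range(10)}))
        report = validate_dataset(ds)
        assert report.valid and not report.warnings

    def test_subject_below_three_measurements_listed(self):
        ds = BPDataset(make_frame({"A": [1, 2, 3], "B": [1, 2, 3], "C": [1, 2]}))
        report = validate_dataset(ds)
        assert not report.valid
        assert "C" in report.offending_subjects
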