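"""Calibration fitting and validation-statistics unit tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dmpk.quantitation import (
    CalibrationStandard,
    QCLevel,
    ThresholdSet,
    Weighting,
    accuracy_precision,
    back_calculate,
    carryover_check,
    compile_validation_report,
    fit_calibration,
    matrix_effect,
    matrix_incubation_remaining,
    predict_response,
    recovery,
    selectivity_check,
    storage_stability,
)
from conftest import TRUE_INTERCEPT, TRUE_SLOPE, make_standards


def wls_normal_equations(x, y, w):
    """Independent brute-force weighted least squares via the normal equations."""
    x, y, w = map(np.asarray, (x, y, w))
    sw, swx, swy = w.sum(), (w * x).sum(), (w * y).sum()
    swxx, swxy = (w * x * x).sum(), (w * x * y).sum()
    det = sw * swxx - swx**2
    intercept = (swxx * swy - swx * swxy) / det
    slope = (sw * swxy - swx * swy) / det
    return slope, intercept


class TestFitCalibration:
    def test_noiseless_recovery_of_generating_line(self, noiseless_standards):
        model = fit_calibration(noiseless_standards, Weighting.ONE_OVER_X2)
        assert model.slope == pytest.approx(TRUE_SLOPE, rel=1e-12)
        assert model.intercept == pytest.approx(TRUE_INTERCEPT, abs=1e-12)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)
        assert (model.lloq, model.uloq) == (0.2, 500.0)

    @pytest.mark.parametrize("weighting", list(Weighting))
    def test_two_points_fit_exactly_any_weighting(self, weighting):
        standards = [
            CalibrationStandard(1.0, 0.029 * 1000, 1000.0),
            CalibrationStandard(10.0, 0.236 * 1000, 1000.0),
        ]
        model = fit_calibration(standards, weighting)
        assert model.slope == pytest.approx(0.023, rel=1e-12)
        assert model.intercept == pytest.approx(0.006, abs=1e-12)

    def test_proportional_noise_slope_within_5pct(self, rng):
        noise = 1.0 + 0.05 * rng.standard_normal(9)
        model = fit_calibration(make_standards(noise=noise))
        assert model.slope == pytest.approx(TRUE_SLOPE, rel=0.05)

    @pytest.mark.parametrize("weighting", list(Weighting))
    def test_matches_normal_equations_oracle(self, rng, weighting):
        """Fit equals an independent normal-equations solve to <= 1e-10 relative."""
        for _ in range(20):
            n = rng.integers(3, 21)
            x = np.sort(rng.uniform(0.2, 500.0, n))
            y = 0.02 * x + 0.01 + rng.normal(0, 0.05, n) * (0.02 * x)
            standards = [CalibrationStandard(xi, yi * 1000, 1000.0) for xi, yi in zip(x, y)]
            model = fit_calibration(standards, weighting)
            slope, intercept = wls_normal_equations(x, y, weighting.weights(x))
            assert model.slope == pytest.approx(slope, rel=1e-10)
            assert model.intercept == pytest.approx(intercept, rel=1e-10, abs=1e-12)

    def test_degenerate_design_raises(self):
        standards = [CalibrationStandard(5.0, 100.0, 1000.0)] * 3
        with pytest.raises(ValueError, match="distinct"):
            fit_calibration(standards)

    def test_standard_with_nonpositive_nominal_rejected(self):
        with pytest.raises(ValueError):
            CalibrationStandard(0.0, 10.0, 1000.0)


class TestBackCalculate:
    def test_algebraic_inverse(self, noiseless_standards):
        model = fit_calibration(noiseless_standards)
        assert back_calculate(model, 2.306).conc == pytest.approx(100.0, rel=1e-9)

    def test_response_at_intercept_is_zero_and_flagged(self, noiseless_standards):
        model = fit_calibration(noiseless_standards)
        res = back_calculate(model, model.intercept)
        assert res.conc == pytest.approx(0.0, abs=1e-12)
        assert res.below_lloq and not res.above_uloq

    def test_round_trip_identity_on_all_standards(self, noiseless_standards):
        model = fit_calibration(noiseless_standards)
        for s in noiseless_standards:
            res = back_calculate(model, predict_response(model, s.nominal_conc))
            assert res.conc == pytest.approx(s.nominal_conc, rel=1e-9)
            assert not res.below_lloq and not res.above_uloq


class TestAccuracyPrecision:
    def test_hand_calculated_bias_and_rsd(self):
        level = QCLevel("LLOQ", 0.2, (0.19, 0.20, 0.21))
        (row,) = accuracy_precision([level], "intra_day")
        assert row.bias_pct == pytest.approx(0.0, abs=1e-9)
        assert row.rsd_pct == pytest.approx(5.0, rel=1e-9)
        assert row.bias_pass and row.rsd_pass

    def test_exact_replicates_have_zero_bias_and_rsd(self):
        level = QCLevel("MQC", 100.0, (100.0, 100.0, 100.0))
        (row,) = accuracy_precision([level], "inter_day")
        assert row.bias_pct == 0.0 and row.rsd_pct == 0.0

    def test_inter_day_pools_across_runs(self):
        levels = [
            QCLevel("HQC", 375.0, (370.0, 380.0), run_id="day1"),
            QCLevel("HQC", 375.0, (360.0, 390.0), run_id="day2"),
        ]
        intra = accuracy_precision(levels, "intra_day")
        inter = accuracy_precision(levels, "inter_day")
        assert len(intra) == 2 and len(inter) == 1
        assert inter[0].n == 4

    def test_five_day_batch_with_known_shift_converges(self, rng):
        """+5% systematic shift, 8% CV: pooled stats near (5%, 8%) at n=15."""
        levels = [
            QCLevel(
                "HQC", 375.0,
                tuple(375.0 * 1.05 * (1 + 0.08 * rng.standard_normal(3))),
                run_id=f"day{d}",
            )
            for d in range(1, 6)
        ]
        (row,) = accuracy_precision(levels, "inter_day")
        assert row.n == 15
        assert 0.0 <= row.bias_pct <= 10.0
        assert 4.0 <= row.rsd_pct <= 14.0
        assert row.bias_pass and row.rsd_pass  # consistent with the 15% limits

    @given(
        values=st.lists(st.floats(50.0, 150.0), min_size=2, max_size=8),
        scale=st.floats(0.1, 100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_bias_rsd_order_and_scale_invariance(self, values, scale):
        nominal = 100.0
        base = accuracy_precision([QCLevel("MQC", nominal, tuple(values))], "inter_day")[0]
        shuffled = accuracy_precision(
            [QCLevel("MQC", nominal, tuple(reversed(values)))], "inter_day"
        )[0]
        scaled = accuracy_precision(
            [QCLevel("MQC", nominal * scale, tuple(v * scale for v in values))], "inter_day"
        )[0]
        assert base.bias_pct == pytest.approx(shuffled.bias_pct, rel=1e-9, abs=1e-9)
        assert base.rsd_pct == pytest.approx(shuffled.rsd_pct, rel=1e-9, abs=1e-9)
        assert base.bias_pct == pytest.approx(scaled.bias_pct, rel=1e-6, abs=1e-8)
        assert base.rsd_pct == pytest.approx(scaled.rsd_pct, rel=1e-6, abs=1e-8)


@pytest.mark.parametrize(
    "extracted, postspiked, expected",
    [
        ([84.0], [100.0], 84.0),
        ([50.0, 60.0], [100.0, 120.0], 50.0),
        ([7.0, 7.0], [7.0, 7.0], 100.0),
    ],
)
def test_recovery(extracted, postspiked, expected):
    assert recovery(extracted, postspiked) == pytest.approx(expected)


@pytest.mark.parametrize(
    "postspiked, neat, expected, passes",
    [
        ([112.0], [100.0], 12.0, True),
        ([100.0], [100.0], 0.0, True),
        ([80.0], [100.0], -20.0, False),
    ],
)
def test_matrix_effect(postspiked, neat, expected, passes):
    me = matrix_effect(postspiked, neat)
    assert me == pytest.approx(expected)
    assert (abs(me) <= ThresholdSet().matrix_effect_limit) is passes


class TestCarryoverSelectivity:
    def test_fractions_and_pass(self):
        res = carryover_check(10.0, 100.0, 1.0, 100.0)
        assert res.analyte_fraction == pytest.approx(0.10)
        assert res.is_fraction == pytest.approx(0.01)
        assert res.passed

    def test_clean_blank_passes(self):
        assert carryover_check(0.0, 100.0, 0.0, 100.0).passed

    def test_excess_analyte_carryover_fails(self):
        res = carryover_check(25.0, 100.0, 1.0, 100.0)
        assert res.analyte_fraction == pytest.approx(0.25)
        assert not res.passed

    def test_selectivity_six_sources(self):
        blanks = [(f * 100.0, 0.0) for f in (0.05, 0.07, 0.09, 0.11, 0.13, 0.15)]
        assert selectivity_check(blanks, 100.0, 100.0).passed

    def test_selectivity_single_bad_source_fails(self):
        blanks = [(0.0, 0.0)] * 5 + [(30.0, 0.0)]
        res = selectivity_check(blanks, 100.0, 100.0)
        assert not res.passed
        assert [r.passed for r in res.per_source] == [True] * 5 + [False]


class TestStability:
    def test_benchtop_magnitude(self):
        pct, ok = storage_stability([0.455], [0.5])
        assert pct == pytest.approx(91.0)
        assert ok

    def test_identity(self):
        pct, ok = storage_stability([0.5, 0.5], [0.5, 0.5])
        assert pct == 100.0 and ok

    def test_fail_outside_window(self):
        pct, ok = storage_stability([0.4], [0.5])
        assert pct == pytest.approx(80.0)
        assert not ok

    @pytest.mark.parametrize(
        "c5, c0, expected", [(5.0, 5.0, 100.0), (2.5, 5.0, 50.0)]
    )
    def test_matrix_incubation_remaining(self, c5, c0, expected):
        assert matrix_incubation_remaining(c5, c0) == pytest.approx(expected)

    def test_matrix_incubation_zero_reference_raises(self):
        with pytest.raises(ValueError):
            matrix_incubation_remaining(1.0, 0.0)


def test_report_flags_are_pure_functions_of_stats(noiseless_standards):
    """The compiled report reproduces every pass flag from stored statistics."""
    qcs = [
        QCLevel("LLOQ", 0.2, (0.19, 0.2, 0.21), run_id="day1"),
        QCLevel("HQC", 375.0, (370.0, 372.0, 379.0), run_id="day1"),
    ]
    report = compile_validation_report(
        standards=noiseless_standards,
        qc_levels=qcs,
        recovery_areas={"LQC": ([84.0], [100.0])},
        matrix_areas={"MQC": ([112.0], [100.0])},
        carryover_responses=(10.0, 100.0, 1.0, 100.0),
        selectivity_blanks=[(0.0, 0.0)] * 6,
        lloq_responses=(100.0, 100.0),
        stability_values={"bench_top": ([0.455], [0.5])},
    )
    d = report.to_dict()
    assert report.overall_pass
    assert d["pass"]["overall"]
    # re-derive a flag from the stored statistic and the stored threshold
    assert (
        abs(d["matrix_effect_pct"]["MQC"]) <= d["thresholds"]["matrix_effect_limit"]
    ) == d["pass"]["matrix_effect"]
    for row in d["accuracy_precision"]:
        limit = 20.0 if row["level"] == "LLOQ" else 15.0
        assert row["bias_pass"] == (abs(row["bias_pct"]) <= limit)
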