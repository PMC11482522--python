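"""clearance: TACs, decay correction, %Cleared, two-phase fits, statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import petmcc as m
from petmcc.clearance import endpoint_value, two_phase_model
from conftest import f_sf_oracle, fisher_exact_enumeration


def _series_from_stack(stack):
    frames = [m.ScalarVolume3D(stack[..., k]) for k in range(stack.shape[-1])]
    times = [(10.0 * k, 10.0 * (k + 1)) for k in range(stack.shape[-1])]
    return m.DynamicSeries(frames, times)


class TestExtractTac:
    def test_whole_grid_roi_equals_total_activity(self, noiseless_phantom):
        spec, branches, ct, labels, series, truth, seed = noiseless_phantom
        roi = m.LabelVolume3D(np.ones(spec.shape, np.uint8), spec.spacing_mm)
        tac = m.extract_tac(series, roi)
        a0 = truth["initial_activity_uci"]
        expected = (
            a0
            * (1 - np.asarray(truth["pct_true"]) / 100.0)
            * 2.0 ** (-np.asarray(truth["times_min"]) / 68.0)
        )
        np.testing.assert_allclose(tac.activity_uci, expected, rtol=1e-9)

    def test_additivity_over_disjoint_rois(self):
        rng = np.random.default_rng(0)
        stack = rng.random((6, 6, 6, 4))
        series = _series_from_stack(stack)
        a = np.zeros((6, 6, 6), np.uint8)
        b = np.zeros((6, 6, 6), np.uint8)
        a[:3] = 1
        b[3:] = 1
        tac_a = m.extract_tac(series, m.LabelVolume3D(a))
        tac_b = m.extract_tac(series, m.LabelVolume3D(b))
        tac_ab = m.extract_tac(series, m.LabelVolume3D(a | b))
        np.testing.assert_allclose(
            tac_ab.activity_uci, tac_a.activity_uci + tac_b.activity_uci
        )

    def test_all_zero_frames_give_zero_tac(self):
        series = _series_from_stack(np.zeros((4, 4, 4, 3)))
        tac = m.extract_tac(series, m.LabelVolume3D(np.ones((4, 4, 4), np.uint8)))
        assert not tac.activity_uci.any()

    def test_empty_roi_rejected(self):
        series = _series_from_stack(np.zeros((4, 4, 4, 3)))
        with pytest.raises(ValueError, match="empty ROI"):
            m.extract_tac(series, m.LabelVolume3D(np.zeros((4, 4, 4), np.uint8)))

    def test_mismatched_geometry_rejected(self):
        series = _series_from_stack(np.zeros((4, 4, 4, 3)))
        roi = m.LabelVolume3D(np.ones((4, 4, 4), np.uint8), spacing=(2, 2, 2))
        with pytest.raises(ValueError, match="geometry"):
            m.extract_tac(series, roi)


class TestDecayCorrect:
    def test_one_half_life_doubles(self):
        tac = m.TimeActivityCurve([0.0, 68.0], [10.0, 5.0])
        out = m.decay_correct(tac, half_life_min=68.0)
        assert out.activity_uci[1] == pytest.approx(10.0)

    def test_reference_time_unchanged(self):
        tac = m.TimeActivityCurve([0.0, 68.0], [10.0, 5.0])
        out = m.decay_correct(tac)
        assert out.activity_uci[0] == pytest.approx(10.0)

    def test_double_correction_rejected(self):
        tac = m.decay_correct(m.TimeActivityCurve([0.0, 1.0], [1.0, 1.0]))
        with pytest.raises(ValueError, match="already"):
            m.decay_correct(tac)


class TestPercentCleared:
    def test_arithmetic(self):
        tac = m.TimeActivityCurve([0.0, 12.0], [10.0, 7.5], decay_corrected=True)
        pc = m.percent_cleared(tac)
        assert pc.pct_cleared[1] == pytest.approx(25.0)
        assert pc.pct_cleared[0] == 0.0

    def test_constant_tac_is_zero_everywhere(self):
        tac = m.TimeActivityCurve([0, 1, 2.0], [4.0, 4.0, 4.0], decay_corrected=True)
        assert not m.percent_cleared(tac).pct_cleared.any()

    def test_inflow_gives_negative_values_unclamped(self):
        tac = m.TimeActivityCurve([0.0, 5.0], [10.0, 12.0], decay_corrected=True)
        assert m.percent_cleared(tac).pct_cleared[1] == pytest.approx(-20.0)

    def test_zero_baseline_rejected(self):
        tac = m.TimeActivityCurve([0.0, 5.0], [0.0, 1.0], decay_corrected=True)
        with pytest.raises(ValueError, match="baseline"):
            m.percent_cleared(tac)

    def test_uncorrected_tac_rejected(self):
        tac = m.TimeActivityCurve([0.0, 5.0], [10.0, 9.0], decay_corrected=False)
        with pytest.raises(ValueError, match="decay-correct"):
            m.percent_cleared(tac)


def _model_curve(f, kf, ks, noise_sd=0.0, rng=None):
    t = np.insert(np.arange(5, 725, 10) / 60.0, 0, 0.0)
    y = two_phase_model(t, f, kf, ks)
    if noise_sd:
        y = y + rng.normal(0, noise_sd, t.size)
    y[0] = 0.0
    return m.ClearanceCurve(t, y, 10.0)


class TestTwoPhaseFit:
    def test_noiseless_recovery(self):
        fit = m.fit_two_phase(_model_curve(0.6, 0.5, 0.02))
        assert fit.f == pytest.approx(0.6, rel=1e-4)
        assert fit.k_fast == pytest.approx(0.5, rel=1e-4)
        assert fit.k_slow == pytest.approx(0.02, rel=1e-4)
        # direct evaluation of the model at the endpoint
        assert fit.predict(12.0) == pytest.approx(68.386160, abs=1e-3)

    def test_single_phase_data_hits_f_boundary(self):
        t = np.insert(np.arange(5, 725, 10) / 60.0, 0, 0.0)
        y = 100.0 * (1 - np.exp(-0.3 * t))
        fit = m.fit_two_phase(m.ClearanceCurve(t, y, 10.0))
        # one-exponential truth: either f -> 1 or both rates coincide
        assert fit.rss == pytest.approx(0.0, abs=1e-6)
        assert fit.predict(t) == pytest.approx(y, abs=1e-3)

    def test_noisy_recovery_of_fast_fraction(self):
        rng = np.random.default_rng(8)
        errs = [
            abs(m.fit_two_phase(_model_curve(0.6, 0.5, 0.02, 1.0, rng)).f - 0.6)
            for _ in range(10)
        ]
        assert np.median(errs) <= 0.05

    def test_fitted_curve_monotone_nondecreasing(self):
        rng = np.random.default_rng(9)
        fit = m.fit_two_phase(_model_curve(0.3, 0.8, 0.01, 2.0, rng))
        t = np.linspace(0, 15, 200)
        assert np.all(np.diff(fit.predict(t)) >= -1e-9)

    def test_label_switching_removed(self):
        fit = m.fit_two_phase(_model_curve(0.4, 1.0, 0.03))
        assert fit.k_fast >= fit.k_slow

    def test_too_few_points_rejected(self):
        c = m.ClearanceCurve([0.0, 1, 2.0], [0.0, 5, 8.0], 10.0)
        with pytest.raises(ValueError, match="at least 4"):
            m.fit_two_phase(c)


class TestFTest:
    def test_equal_rss_gives_f0_p1(self):
        g = m.TwoPhaseFit(0.5, 1.0, 0.01, rss=10.0, n_obs=23)
        s = [m.TwoPhaseFit(0.5, 1.0, 0.01, rss=5.0, n_obs=12),
             m.TwoPhaseFit(0.5, 1.0, 0.01, rss=5.0, n_obs=11)]
        res = m.compare_fits_f_test(g, s)
        assert res.F == 0.0
        assert res.p == 1.0

    def test_known_rss_values_match_f_distribution_oracle(self):
        g = m.TwoPhaseFit(0.5, 1.0, 0.01, rss=12.0, n_obs=23)   # df = 20
        s = [m.TwoPhaseFit(0.5, 1.0, 0.01, rss=4.0, n_obs=12),  # pooled df = 18
             m.TwoPhaseFit(0.5, 1.0, 0.01, rss=6.0, n_obs=11, n_params=2)]
        res = m.compare_fits_f_test(g, s)
        assert res.F == pytest.approx(1.8)
        assert (res.df_num, res.df_den) == (2, 18)
        assert res.p == pytest.approx(f_sf_oracle(1.8, 2, 18), abs=1e-12)
        assert res.p == pytest.approx(0.194, abs=5e-3)

    def test_worse_separate_fit_clamped_with_warning(self):
        g = m.TwoPhaseFit(0.5, 1.0, 0.01, rss=10.0, n_obs=23)
        s = [m.TwoPhaseFit(0.5, 1.0, 0.01, rss=6.0, n_obs=12),
             m.TwoPhaseFit(0.5, 1.0, 0.01, rss=6.0, n_obs=11)]
        with pytest.warns(UserWarning, match="clamp"):
            res = m.compare_fits_f_test(g, s)
        assert res.F == 0.0

    def test_distinct_groups_detected(self):
        rng = np.random.default_rng(10)
        a = [_model_curve(0.6, 0.5, 0.02, 1.0, rng) for _ in range(6)]
        b = [_model_curve(0.2, 0.3, 0.005, 1.0, rng) for _ in range(6)]
        fg = m.fit_two_phase(a + b)
        fs = [m.fit_two_phase(a), m.fit_two_phase(b)]
        assert m.compare_fits_f_test(fg, fs).p < 1e-6


def _curve_with_endpoint(pct12, group="g", sid=""):
    t = np.array([0.0, 6.0, 12.0])
    return m.ClearanceCurve(t, np.array([0.0, pct12 / 2, pct12]), 10.0, sid, group)


class TestResponders:
    def test_counts_above_strict_threshold(self):
        g1 = [_curve_with_endpoint(v, "a") for v in (25.0, 15.0, 21.0)]
        g2 = [_curve_with_endpoint(v, "b") for v in (5.0, 30.0)]
        tab = m.classify_responders({"a": g1, "b": g2})
        np.testing.assert_array_equal(tab.table, [[2, 1], [1, 1]])

    def test_exactly_threshold_is_nonresponder(self):
        tab = m.classify_responders(
            {"a": [_curve_with_endpoint(20.0, "a")], "b": [_curve_with_endpoint(21.0, "b")]}
        )
        np.testing.assert_array_equal(tab.table, [[0, 1], [1, 0]])

    def test_empty_group_zero_row_with_warning(self):
        with pytest.warns(UserWarning, match="zero row"):
            tab = m.classify_responders({"a": [], "b": [_curve_with_endpoint(25.0, "b")]})
        np.testing.assert_array_equal(tab.table, [[0, 0], [1, 0]])

    def test_short_curve_excluded_with_warning(self):
        short = m.ClearanceCurve([0.0, 2.0], [0.0, 30.0], 10.0, "s", "a")
        with pytest.warns(UserWarning, match="excluded"):
            tab = m.classify_responders(
                {"a": [short, _curve_with_endpoint(25.0, "a")],
                 "b": [_curve_with_endpoint(10.0, "b")]}
            )
        np.testing.assert_array_equal(tab.table, [[1, 0], [0, 1]])

    def test_endpoint_interpolates_between_frames(self):
        c = m.ClearanceCurve([0.0, 8.0, 16.0], [0.0, 10.0, 30.0], 10.0)
        assert endpoint_value(c, 12.0) == pytest.approx(20.0)


class TestFisher:
    def test_enumeration_value_3113(self):
        p = m.fisher_exact(m.Contingency2x2(3, 1, 1, 3))
        assert p == pytest.approx(34 / 70, abs=1e-12)

    def test_enumeration_value_2002(self):
        p = m.fisher_exact(m.Contingency2x2(2, 0, 0, 2))
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_rows_p1(self):
        assert m.fisher_exact(m.Contingency2x2(3, 2, 3, 2)) == pytest.approx(1.0)

    def test_zero_margin_warns_p1(self):
        with pytest.warns(UserWarning, match="zero margin"):
            assert m.fisher_exact(m.Contingency2x2(0, 0, 3, 2)) == 1.0

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.tuples(*[st.integers(0, 8)] * 4))
    def test_matches_exhaustive_enumeration(self, counts):
        a, b, c, d = counts
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        p = m.fisher_exact(m.Contingency2x2(a, b, c, d))
        assert p == pytest.approx(fisher_exact_enumeration(a, b, c, d), abs=1e-9)


class TestGroupSummary:
    def test_mean_and_se(self):
        curves = {"g": [_curve_with_endpoint(20.0), _curve_with_endpoint(30.0)]}
        out = m.group_summary(curves)
        assert out["g"]["mean"] == pytest.approx(25.0)
        assert out["g"]["se"] == pytest.approx(5.0)

    def test_equal_values_zero_se(self):
        curves = {"g": [_curve_with_endpoint(15.0)] * 3}
        assert m.group_summary(curves)["g"]["se"] == pytest.approx(0.0)

    def test_single_curve_se_absent(self):
        out = m.group_summary({"g": [_curve_with_endpoint(15.0)]})
        assert out["g"]["se"] is None
        assert out["g"]["n"] == 1
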