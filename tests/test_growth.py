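"""Log-linear calibration, boundary-condition model and doubling time."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq

import capgrow as cg
from capgrow.growth import InsufficientDataError


def make_counts(t_s, counts):
    return cg.CellCountSeries(np.asarray(t_s, float), np.asarray(counts, float))


def make_trend(t_s, y):
    return cg.TrendCurve(np.asarray(t_s, float), np.asarray(y, float),
                         sg_order=3, sg_window=5)


class TestAlign:
    def test_identical_grids_keep_all_pairs(self):
        t = np.arange(0, 3600 * 2, 300.0)
        counts = make_counts(t, np.linspace(10, 40, t.size))
        trend = make_trend(t, np.linspace(0, 50, t.size))
        pairs = cg.align_series(counts, trend)
        assert len(pairs) == t.size
        assert np.allclose(pairs.delta_c_aF, trend.delta_c_aF)

    def test_nearest_rule_prefers_closer_sample(self):
        counts = make_counts([300.0, 600.0, 900.0], [10.0, 20.0, 30.0])
        trend = make_trend([290.0, 319.0, 580.0, 610.0, 895.0, 930.0],
                           [1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        pairs = cg.align_series(counts, trend)
        # 300 -> 290 (10 s closer than 319); 600 -> 610; 900 -> 895
        assert np.allclose(pairs.delta_c_aF, [1.0, 4.0, 5.0])

    def test_all_zero_counts_is_insufficient(self):
        t = np.arange(0, 1500, 300.0)
        counts = make_counts(t, np.zeros(t.size))
        trend = make_trend(t, np.linspace(0, 5, t.size))
        with pytest.raises(InsufficientDataError):
            with pytest.warns(UserWarning):
                cg.align_series(counts, trend)

    def test_out_of_tolerance_counts_dropped_with_warning(self):
        counts = make_counts([0.0, 300.0, 600.0, 5000.0], [5.0, 6.0, 7.0, 8.0])
        trend = make_trend([0.0, 290.0, 580.0, 900.0], [1.0, 2.0, 3.0, 4.0])
        with pytest.warns(UserWarning, match="dropped 1 counts"):
            pairs = cg.align_series(counts, trend, tol_s=150.0)
        assert len(pairs) == 3


class TestLogLinearFit:
    def test_exact_line_recovered(self):
        dc = np.linspace(0, 300, 40)
        t = np.arange(40) * 300.0
        counts = np.exp(0.007 * dc + 6.0)
        pairs = cg.align_series(make_counts(t, counts), make_trend(t, dc))
        fit = cg.fit_loglinear(pairs)
        assert fit.alpha == pytest.approx(0.007, abs=1e-10)
        assert fit.K == pytest.approx(6.0, abs=1e-10)
        assert fit.pearson_r == pytest.approx(1.0, abs=1e-10)

    def test_three_hand_picked_points(self):
        pairs = cg.PairedSeries([0.0, 1.0, 2.0], [1.0, 2.0, 3.0], [0.0, 1.0, 2.0])
        fit = cg.fit_loglinear(pairs)
        assert fit.alpha == pytest.approx(1.0)
        assert fit.K == pytest.approx(1.0)
        assert fit.pearson_r == pytest.approx(1.0)

    def test_constant_regressor_rejected(self):
        pairs = cg.PairedSeries([0.0, 1.0, 2.0], [1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        with pytest.raises(ValueError, match="constant"):
            cg.fit_loglinear(pairs)


class TestGeneralizedModel:
    def test_zero_intercept_gives_unit_scale(self):
        fit = cg.LogLinearFit(0.01, 0.0, 1.0, 0.0, 10)
        assert cg.build_generalized(fit, 3.38).A == 1.0

    def test_direct_evaluation(self):
        fit = cg.LogLinearFit(0.0231, 6.0, 1.0, 0.0, 10)
        model = cg.build_generalized(fit, 1.0)
        assert cg.predict(model, 30.0) == pytest.approx(math.exp(6.0) * 2.0, rel=1e-3)

    def test_zero_rate_is_constant(self):
        fit = cg.LogLinearFit(0.0, 2.0, 1.0, 0.0, 10)
        model = cg.build_generalized(fit, 3.38)
        assert np.allclose(model.predict([0.0, 10.0, 20.0]), math.exp(2.0))


class TestParticularModel:
    def test_exact_doubling_zero_offset(self):
        m = cg.fit_particular(1.0, 0.0231, 400.0, 0.0, 800.0, 30.0)
        assert m.Gamma == pytest.approx(400.0, rel=1e-3)
        assert m.beta == pytest.approx(0.0, abs=0.5)

    def test_hand_solved_two_by_two_system(self):
        # e^{0.0231*30} = 2 (to 3 digits): Gamma=400, beta=100
        x = math.log(2.0) / 30.0
        m = cg.fit_particular(x, 1.0, 500.0, 0.0, 900.0, 30.0)
        assert m.Gamma == pytest.approx(400.0, rel=1e-12)
        assert m.beta == pytest.approx(100.0, rel=1e-12)

    def test_flat_boundaries_give_constant_model(self):
        m = cg.fit_particular(0.01, 3.38, 250.0, 0.0, 250.0, 30.0)
        assert m.Gamma == 0.0
        assert m.beta == 250.0
        assert cg.predict(m, 17.0) == pytest.approx(250.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            cg.fit_particular(0.0, 3.38, 100.0, 0.0, 200.0, 30.0)
        with pytest.raises(ValueError):
            cg.fit_particular(0.01, 3.38, 100.0, 10.0, 200.0, 10.0)
        with pytest.raises(ValueError):
            cg.fit_particular(0.01, 3.38, -5.0, 0.0, 200.0, 30.0)

    def test_predict_hits_boundaries_exactly(self):
        m = cg.fit_particular(0.008, 3.38, 123.0, 2.0, 456.0, 28.0)
        assert cg.predict(m, 2.0) == pytest.approx(123.0, rel=1e-12)
        assert cg.predict(m, 28.0) == pytest.approx(456.0, rel=1e-12)

    def test_predict_midpoint_value(self):
        x = math.log(2.0) / 30.0  # alpha*S_avg = 0.0231 to 3 digits
        m = cg.fit_particular(x, 1.0, 500.0, 0.0, 900.0, 30.0)
        assert cg.predict(m, 15.0) == pytest.approx(400.0 * math.sqrt(2) + 100.0,
                                                    rel=1e-12)

    def test_predict_monotone_for_positive_growth(self):
        m = cg.fit_particular(0.008, 3.38, 100.0, 0.0, 300.0, 30.0)
        t = np.linspace(0, 30, 301)
        assert np.all(np.diff(cg.predict(m, t)) > 0)


class TestGoodnessOfFit:
    def test_model_generated_counts_fit_perfectly(self):
        m = cg.fit_particular(0.008, 3.38, 200.0, 0.0, 500.0, 30.0)
        t_h = np.linspace(0, 30, 25)
        counts = make_counts(t_h * 3600.0, cg.predict(m, t_h))
        fq = cg.goodness_of_fit(m, counts)
        assert fq.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fq.adj_r_squared == pytest.approx(1.0, abs=1e-12)

    def test_adjustment_formula(self):
        # R2=0.9, n=20, k=3 -> adj = 1 - 0.1*19/16 = 0.88125
        assert 1 - (1 - 0.9) * 19 / 16 == pytest.approx(0.88125)
        m = cg.fit_particular(0.008, 3.38, 200.0, 0.0, 500.0, 30.0)
        rng = np.random.default_rng(3)
        t_h = np.linspace(0, 30, 20)
        y = cg.predict(m, t_h) + rng.normal(0, 25, 20)
        fq = cg.goodness_of_fit(m, make_counts(t_h * 3600.0, np.abs(y)))
        expected = 1 - (1 - fq.r_squared) * (20 - 1) / (20 - 3 - 1)
        assert fq.adj_r_squared == pytest.approx(expected, rel=1e-12)
        assert fq.adj_r_squared <= fq.r_squared

    def test_zero_variance_counts_rejected(self):
        m = cg.fit_particular(0.008, 3.38, 200.0, 0.0, 500.0, 30.0)
        counts = make_counts(np.arange(6) * 3600.0, np.full(6, 200.0))
        with pytest.raises(ValueError, match="variance"):
            cg.goodness_of_fit(m, counts)


class TestDoublingTime:
    def test_zero_offset_closed_form(self):
        nf = 400.0 * math.exp(0.0231 * 30.0)  # beta exactly 0
        m = cg.fit_particular(0.0231, 1.0, 400.0, 0.0, nf, 30.0)
        assert m.beta == pytest.approx(0.0, abs=1e-9)
        td = cg.doubling_time(m, window_end_h=40.0)
        assert td.t_d_h == pytest.approx(math.log(2.0) / 0.0231, rel=1e-9)

    def test_offset_model_beyond_window_undefined(self):
        # Gamma=400, beta=100, N0=500: t_d = ln(900/400)/0.0231 ≈ 35.1 h
        m = cg.ParticularModel(400.0, 100.0, 0.0231, 1.0, 0.0, 30.0, 500.0, 900.0)
        td = cg.doubling_time(m, window_end_h=30.0)
        assert td.t_d_h is None and not td.within_window
        assert td.t_d_extrapolated_h == pytest.approx(
            math.log(900.0 / 400.0) / 0.0231, rel=1e-9
        )

    def test_no_doubling_when_nf_below_two_n0(self):
        m = cg.fit_particular(0.008, 1.0, 300.0, 0.0, 500.0, 30.0)
        td = cg.doubling_time(m, window_end_h=30.0)
        assert not td.within_window  # monotone model cannot double before tn

    def test_flat_model_undefined(self):
        m = cg.fit_particular(0.01, 3.38, 250.0, 0.0, 250.0, 30.0)
        td = cg.doubling_time(m, window_end_h=30.0)
        assert td.t_d_h is None and not td.within_window

    def test_matches_bisection_root(self):
        m = cg.fit_particular(0.0079, 3.38, 320.0, 1.0, 780.0, 29.0)
        td = cg.doubling_time(m, window_end_h=50.0)
        root = brentq(lambda t: cg.predict(m, m.t0_h + t) - 2 * m.N0, 1e-9, 100.0,
                      xtol=1e-12)
        assert td.t_d_h == pytest.approx(root, abs=1e-6)


@given(
    rate=st.floats(0.005, 0.06),
    n0=st.floats(50.0, 1000.0),
    growth=st.floats(1.05, 4.0),
    t0=st.floats(0.0, 5.0),
    span=st.floats(5.0, 40.0),
)
def test_boundary_conditions_always_satisfied(rate, n0, growth, t0, span):
    m = cg.fit_particular(rate, 1.0, n0, t0, n0 * growth, t0 + span)
    assert abs(cg.predict(m, m.t0_h) - m.N0) / m.N0 < 1e-10
    assert abs(cg.predict(m, m.tn_h) - m.Nf) / m.Nf < 1e-10
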