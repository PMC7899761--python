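"""MFL metric, per-window assignment, gradient and nonlinear-model fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgfatigue.fatigue import (GradientFit, anchor_mfl, assign_mfl,
                                fit_gradient, fit_nonlinear,
                                fit_session_gradient, mfl_basic, mfl_static)
from emgfatigue.features import extract_features, select_steady
from emgfatigue.synthgen import (SessionProtocolSpec, SessionRecord,
                                 simulate_session)


class TestMflMetric:
    @pytest.mark.parametrize("mvc_t,expect", [(500, 0.0), (400, 0.2), (0, 1.0)])
    def test_basic_ratio(self, mvc_t, expect):
        assert mfl_basic(500.0, mvc_t) == pytest.approx(expect)

    def test_basic_rejects_nonpositive_initial(self):
        with pytest.raises(ValueError):
            mfl_basic(0.0, 100.0)

    def test_static_endpoints(self):
        # fresh: current MVC equals initial; exhausted: it equals required
        assert mfl_static(500.0, 500.0, 250.0) == 0.0
        assert mfl_static(500.0, 250.0, 250.0) == 1.0

    def test_static_midpoint(self):
        assert mfl_static(500.0, 400.0, 300.0) == pytest.approx(0.5)

    def test_static_clips_and_raw_mode(self):
        assert mfl_static(500.0, 600.0, 250.0) == 0.0
        assert mfl_static(500.0, 100.0, 250.0) == 1.0
        assert mfl_static(500.0, 100.0, 250.0, clip=False) == pytest.approx(1.6)

    def test_degenerate_session_rejected(self):
        with pytest.raises(ValueError):
            mfl_static(250.0, 200.0, 250.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(mvc_i=st.floats(10, 1000), frac_f=st.floats(0.01, 0.95),
           t1=st.floats(0, 1), t2=st.floats(0, 1), c=st.floats(0.1, 10))
    def test_monotone_in_mvc_t_and_scale_invariant(self, mvc_i, frac_f,
                                                   t1, t2, c):
        mvc_f = frac_f * mvc_i
        lo, hi = sorted([t1, t2])
        v_lo = mvc_f + lo * (mvc_i - mvc_f)
        v_hi = mvc_f + hi * (mvc_i - mvc_f)
        # larger remaining MVC -> less fatigue
        assert mfl_static(mvc_i, v_hi, mvc_f) <= mfl_static(mvc_i, v_lo, mvc_f)
        assert mfl_static(c * mvc_i, c * v_lo, c * mvc_f) == pytest.approx(
            mfl_static(mvc_i, v_lo, mvc_f), rel=1e-9)


class TestAssignment:
    def session(self):
        return SessionRecord(500.0, 250.0, [(0.0, 500.0), (15.0, 425.0)],
                             [(5.0, 15.0, 250.0)])

    def test_anchor_times_exact(self):
        s = self.session()
        out = assign_mfl(s, [0.0, 15.0])
        assert np.allclose(out, [0.0, 0.3])

    def test_linear_interpolation_between_anchors(self):
        out = assign_mfl(self.session(), [5.0])
        assert out[0] == pytest.approx(0.1)

    def test_constant_extrapolation(self):
        out = assign_mfl(self.session(), [-1.0, 30.0])
        assert np.allclose(out, [0.0, 0.3])

    def test_empty_session_rejected(self):
        s = SessionRecord(500.0, 250.0, [], [])
        with pytest.raises(ValueError):
            assign_mfl(s, [1.0])

    def test_noiseless_session_assignment_matches_ground_truth(self):
        spec = SessionProtocolSpec(target_level=0.6, gradient=0.02,
                                   tremor_sd=0.0, mvc_noise_sd=0.0, seed=1)
        bundle = simulate_session(spec)
        fm = select_steady(extract_features(bundle), bundle)
        assigned = assign_mfl(bundle.session, fm.window_times)
        truth = np.clip(spec.gradient * fm.window_times, 0, 1)
        pre_saturation = truth < 1.0
        assert np.allclose(assigned[pre_saturation], truth[pre_saturation],
                           atol=1e-9)


class TestGradientFit:
    def test_exact_line_recovered(self):
        t = np.arange(30.0)
        fit = fit_gradient(t, 0.0532 * t)
        assert fit.slope == pytest.approx(0.0532, abs=1e-12)
        assert fit.r2_fit == pytest.approx(1.0, abs=1e-12)
        assert fit.ci95_slope[0] <= fit.slope <= fit.ci95_slope[1]

    def test_constant_input_gives_zero_slope(self):
        fit = fit_gradient(np.arange(10.0), np.full(10, 0.4))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_gradient([1.0, 2.0], [0.1, 0.2])
        with pytest.raises(ValueError, match="singular"):
            fit_gradient([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])

    def test_ci_coverage_of_true_slope(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 30, 30)
        hits = 0
        for _ in range(100):
            y = 0.02 * t + rng.normal(0, 0.02, t.size)
            fit = fit_gradient(t, y)
            hits += fit.ci95_slope[0] <= 0.02 <= fit.ci95_slope[1]
        assert hits >= 90

    @pytest.mark.parametrize("level,gradient",
                             [(0.5, 0.0077), (0.6, 0.0108), (0.7, 0.0532)])
    def test_session_anchor_slopes_recover_fatigue_rates(self, level,
                                                         gradient):
        """Mean anchor-fit slope over 20 noisy sessions within 5% of truth."""
        slopes = []
        for seed in range(20):
            spec = SessionProtocolSpec(target_level=level, gradient=gradient,
                                       mvc_i=500.0, mvc_noise_sd=2.0,
                                       tremor_sd=0.0, seed=seed)
            slopes.append(fit_session_gradient(simulate_session(spec)).slope)
        assert np.mean(slopes) == pytest.approx(gradient, rel=0.05)

    def test_per_level_slope_ordering_preserved(self):
        """Faster injected fatigue rates yield larger fitted slopes."""
        for seed in range(5):
            fitted = []
            for level, g in [(0.5, 0.0077), (0.6, 0.0108), (0.7, 0.0532)]:
                spec = SessionProtocolSpec(target_level=level, gradient=g,
                                           mvc_noise_sd=2.0, seed=seed)
                fitted.append(fit_session_gradient(simulate_session(spec)).slope)
            assert fitted[0] < fitted[1] < fitted[2]


class TestNonlinearModel:
    @staticmethod
    def make_data(a, b, c, levels=(0.5, 0.6, 0.7)):
        out = []
        for lv in levels:
            t = np.linspace(0, 60, 40)
            out.append((lv, t, a * np.exp(b * lv) * t + c))
        return out

    def test_parameters_recovered_on_noiseless_data(self):
        model = fit_nonlinear(self.make_data(0.001, 5.6, 0.0))
        assert model.a == pytest.approx(0.001, rel=1e-6)
        assert model.b == pytest.approx(5.6, rel=1e-6)
        assert model.c == pytest.approx(0.0, abs=1e-6)
        assert model.rss < 1e-12

    def test_flat_level_dependence_reduces_to_common_slope(self):
        model = fit_nonlinear(self.make_data(0.005, 0.0, 0.0))
        assert model.b == pytest.approx(0.0, abs=1e-6)
        assert model.a == pytest.approx(0.005, rel=1e-6)

    def test_single_level_unidentifiable(self):
        with pytest.raises(ValueError):
            fit_nonlinear(self.make_data(0.001, 5.6, 0.0, levels=(0.6,)))
        with pytest.raises(ValueError):
            fit_nonlinear(self.make_data(0.001, 5.6, 0.0, levels=(0.6, 0.6)))

    def test_prediction_clipped_to_unit_interval(self):
        model = fit_nonlinear(self.make_data(0.001, 5.6, 0.0))
        assert np.all(model.predict(0.7, np.array([0.0, 1e5])) <= 1.0)
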