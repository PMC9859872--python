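"""4PL fitting, confidence bands and detection limits."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lfaquant import (SimulationConfig, confidence_band, detection_limits,
                      fit_4pl, fourpl_response, normalize)
from lfaquant.calibrate import (bootstrap_band, compare_conjugates, to_points)
from lfaquant.errors import DomainError, LimitError, NormalizationError
from lfaquant.simulate import simulate_normalized_signals

CONCS = np.array([0.0, 1.0, 10.0, 30.0, 100.0, 300.0, 1000.0, 10000.0])


class TestFourPLModel:
    @settings(deadline=None, derandomize=True)
    @given(a1=st.floats(0.2, 2.0), a2=st.floats(-0.5, 0.15),
           x0=st.floats(0.1, 1e4), p=st.floats(0.1, 5.0))
    def test_midpoint_identity(self, a1, a2, x0, p):
        assert fourpl_response(x0, a1, a2, x0, p) == pytest.approx(
            (a1 + a2) / 2, rel=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(a1=st.floats(0.5, 2.0), a2=st.floats(-0.5, 0.3),
           x0=st.floats(0.1, 1e4), p=st.floats(0.1, 5.0))
    def test_monotone_decreasing_when_a1_gt_a2(self, a1, a2, x0, p):
        if a1 <= a2:
            return
        x = np.geomspace(1e-3, 1e6, 50)
        y = fourpl_response(x, a1, a2, x0, p)
        assert np.all(np.diff(y) < 1e-15)

    def test_zero_concentration_is_upper_asymptote(self):
        assert fourpl_response(0.0, 1.0, 0.1, 50.0, 1.2) == 1.0


class TestNormalize:
    def test_divides_by_blank_mean(self):
        t = pd.DataFrame({"concentration": [0.0, 10.0], "signal": [2.0, 1.0]})
        out = normalize(t)
        assert out["normalized"].tolist() == [1.0, 0.5]

    def test_blank_mean_is_exactly_one(self):
        t = pd.DataFrame({"concentration": [0.0, 0.0, 10.0],
                          "signal": [1.8, 2.2, 1.0]})
        out = normalize(t)
        assert out.loc[out["concentration"] == 0, "normalized"].mean() == 1.0

    def test_missing_or_degenerate_blank(self):
        with pytest.raises(NormalizationError):
            normalize(pd.DataFrame({"concentration": [1.0], "signal": [1.0]}))
        with pytest.raises(NormalizationError):
            normalize(pd.DataFrame({"concentration": [0.0, 1.0],
                                    "signal": [0.0, 1.0]}))

    def test_points_grouping(self):
        t = normalize(pd.DataFrame({"concentration": [0.0, 0.0, 10.0],
                                    "signal": [2.0, 2.0, 1.0]}))
        pts = to_points(t)
        assert [p.concentration for p in pts] == [0.0, 10.0]
        assert pts[0].normalized == (1.0, 1.0)


class TestFit4PL:
    def test_noiseless_recovery_to_machine_tolerance(self):
        y = fourpl_response(CONCS, 1.0, 0.1, 50.0, 1.2)
        fit = fit_4pl(CONCS, y)
        np.testing.assert_allclose(fit.params, [1.0, 0.1, 50.0, 1.2],
                                   rtol=1e-6)
        assert fit.residual_variance < 1e-12

    def test_monte_carlo_ec50_unbiased(self):
        cfg = SimulationConfig()
        rng = np.random.default_rng(11)
        x0s = []
        for _ in range(500):
            c, y = simulate_normalized_signals(cfg, 0.03, 4, rng=rng)
            x0s.append(fit_4pl(c, y).x0)
        se = np.std(x0s, ddof=1) / np.sqrt(len(x0s))
        assert np.mean(x0s) == pytest.approx(50.0, abs=2 * se)

    def test_orientation_warning_for_increasing_data(self):
        y = fourpl_response(CONCS, 0.1, 1.0, 50.0, 1.2)  # increasing
        with pytest.warns(UserWarning, match="orientation"):
            fit_4pl(CONCS, y)

    def test_insufficient_design_rejected(self):
        with pytest.raises(DomainError):
            fit_4pl([0.0, 1.0, 10.0, 100.0], [1.0, 0.9, 0.5, 0.2])
        with pytest.raises(DomainError):
            fit_4pl([1.0, 10.0, 30.0, 100.0, 300.0],
                    [0.9, 0.8, 0.6, 0.4, 0.2])


class TestConfidenceBand:
    def test_zero_residual_variance_collapses_band(self):
        y = fourpl_response(CONCS, 1.0, 0.1, 50.0, 1.2)
        fit = fit_4pl(CONCS, y)
        x = np.array([0.0, 5.0, 50.0, 500.0])
        lo, hi = confidence_band(fit, x, 0.95)
        np.testing.assert_allclose(lo, fit.predict(x), atol=1e-6)
        np.testing.assert_allclose(hi, fit.predict(x), atol=1e-6)

    def test_level_zero_collapses_band(self, noisy_fit):
        x = np.array([0.0, 10.0, 100.0])
        lo, hi = confidence_band(noisy_fit, x, 0.0)
        np.testing.assert_allclose(lo, noisy_fit.predict(x), atol=1e-12)
        np.testing.assert_allclose(hi, noisy_fit.predict(x), atol=1e-12)

    def test_prediction_band_contains_confidence_band(self, noisy_fit):
        x = np.geomspace(0.1, 1e4, 20)
        clo, chi = confidence_band(noisy_fit, x, 0.95, kind="confidence")
        plo, phi = confidence_band(noisy_fit, x, 0.95, kind="prediction")
        assert np.all(plo <= clo) and np.all(phi >= chi)

    def test_delta_method_agrees_with_parametric_bootstrap(self, noisy_fit):
        x = np.geomspace(0.5, 5e3, 15)
        dlo, dhi = confidence_band(noisy_fit, x, 0.95)
        blo, bhi = bootstrap_band(noisy_fit, x, 0.95, n_boot=2000, seed=1)
        half = (dhi - dlo) / 2
        disagreement = np.concatenate([np.abs(dlo - blo), np.abs(dhi - bhi)])
        assert np.median(disagreement) < 0.10 * np.median(half)


class TestDetectionLimits:
    def test_band_collapse_sends_limits_to_zero(self):
        y = fourpl_response(CONCS, 1.0, 0.1, 50.0, 1.2)
        fit = fit_4pl(CONCS, y)
        lim = detection_limits(fit, bracket=(1e-3, 1e5))
        assert lim.mdc <= 1e-3 + 1e-9
        assert lim.rdl <= 1e-2

    def test_mdc_not_above_rdl(self):
        cfg = SimulationConfig()
        for seed in range(5):
            c, y = simulate_normalized_signals(
                cfg, 0.03, 4, rng=np.random.default_rng(seed))
            lim = detection_limits(fit_4pl(c, y))
            assert 0 < lim.mdc <= lim.rdl
            assert lim.mdc < lim.ec50

    def test_critical_level_is_lower_band_at_zero(self, noisy_fit):
        lim = detection_limits(noisy_fit)
        lo0 = confidence_band(noisy_fit, 0.0, 0.95)[0][0]
        assert lim.y_crit == pytest.approx(lo0)
        # the curve crosses the critical level exactly at the MDC
        assert noisy_fit.predict(lim.mdc) == pytest.approx(lim.y_crit,
                                                           rel=1e-5)
        # and the upper band at the RDL
        hi = confidence_band(noisy_fit, lim.rdl, 0.95)[1][0]
        assert hi == pytest.approx(lim.y_crit, rel=1e-5)

    def test_limit_beyond_bracket_raises(self, noisy_fit):
        with pytest.raises(LimitError):
            detection_limits(noisy_fit, bracket=(1e-3, 1e-2), n_grid=20)

    def test_increasing_curve_rejected(self):
        y = fourpl_response(CONCS, 0.1, 1.0, 50.0, 1.2)
        with pytest.warns(UserWarning, match="orientation"):
            fit = fit_4pl(CONCS, y)
        with pytest.raises(DomainError):
            detection_limits(fit)


class TestCompareConjugates:
    def _batch(self, x0, sigma, seed):
        cfg = SimulationConfig(x0=x0)
        c, y = simulate_normalized_signals(cfg, sigma, 4,
                                           rng=np.random.default_rng(seed))
        fit = fit_4pl(c, y)
        return fit, detection_limits(fit)

    def test_identical_triplicates_have_zero_se(self):
        b = self._batch(50.0, 0.02, 1)
        df = compare_conjugates({"A": [b, b, b]})
        assert df.loc[0, "ec50_se"] == pytest.approx(0.0, abs=1e-12)

    def test_known_triplicate_mean(self):
        batches = [self._batch(x0, 0.0, 0) for x0 in (40.0, 50.0, 60.0)]
        df = compare_conjugates({"A": batches})
        assert df.loc[0, "ec50_mean"] == pytest.approx(50.0, rel=1e-4)

    def test_weak_conjugate_gets_larger_mdc(self):
        good = [self._batch(50.0, 0.01, s) for s in (1, 2, 3)]
        weak = [self._batch(50.0, 0.08, s) for s in (4, 5, 6)]
        df = compare_conjugates({"good": good, "weak": weak}).set_index("label")
        assert df.loc["weak", "mdc_mean"] > df.loc["good", "mdc_mean"]
        # ranking is by MDC: the good conjugate comes first
        assert compare_conjugates({"good": good, "weak": weak})\
            .iloc[0]["label"] == "good"
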