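"""Melting analysis: central difference, T_M, FWHM, AUC, detection, dT_M."""

import numpy as np
import pytest

import laurdan_gp as lg
from laurdan_gp.errors import (
    InsufficientPointsError,
    NoTransitionError,
    TruncatedPeakError,
)

# analytic FWHM of the derivative of a logistic transition of width k
LOGISTIC_FWHM_FACTOR = 2.0 * np.log(3.0 + 2.0 * np.sqrt(2.0))


def logistic_curve(factory, tm, k, t_min, t_max, step, gp_gel=0.55, gp_fluid=-0.15):
    t = np.arange(t_min, t_max + step / 2, step)
    f = 1.0 / (1.0 + np.exp((t - tm) / k))
    return factory(t, gp_fluid + (gp_gel - gp_fluid) * f)


class TestCentralDifference:
    def test_constant_gp_has_zero_derivative(self, gp_curve_factory):
        d = lg.central_difference(gp_curve_factory(np.arange(5.0), np.full(5, 0.3)))
        assert np.allclose(d.neg_dgp_dt, 0.0)
        assert len(d) == 3

    def test_exact_for_affine_gp_on_any_grid(self, gp_curve_factory):
        t = np.array([0.0, 1.0, 2.5, 3.0, 7.0])  # non-uniform
        curve = gp_curve_factory(t, -0.02 * t)
        d = lg.central_difference(curve)
        assert np.allclose(d.neg_dgp_dt, 0.02)
        assert np.array_equal(d.temperatures_C, t[1:-1])

    def test_exact_for_quadratic_on_uniform_grid(self, gp_curve_factory):
        t = np.arange(0.0, 11.0)
        d = lg.central_difference(gp_curve_factory(t, (t**2) / 200.0))
        # dGP/dT at T=5 is 2*5/200; sign-flipped in the output
        i = np.flatnonzero(d.temperatures_C == 5.0)[0]
        assert d.neg_dgp_dt[i] == pytest.approx(-10.0 / 200.0, abs=1e-15)

    def test_second_order_convergence_on_cubic(self, gp_curve_factory):
        # error of the centered stencil on T^3 is exactly h^2 at every point
        def max_err(h):
            t = np.arange(-2.0, 2.0 + h / 2, h)
            d = lg.central_difference(gp_curve_factory(t, (t**3) / 100.0))
            exact = -3.0 * d.temperatures_C**2 / 100.0
            return np.max(np.abs(d.neg_dgp_dt - exact))

        assert max_err(0.1) / max_err(0.2) == pytest.approx(0.25, rel=1e-6)

    def test_too_few_points(self, gp_curve_factory):
        with pytest.raises(InsufficientPointsError):
            lg.central_difference(gp_curve_factory([0.0, 1.0], [0.1, 0.2]))


class TestFindTm:
    def deriv(self, temps, vals):
        return lg.DerivativeCurve(
            temperatures_C=np.asarray(temps, float),
            neg_dgp_dt=np.asarray(vals, float),
        )

    def test_grid_argmax(self):
        assert lg.find_tm(self.deriv([23, 24, 25], [0.1, 0.5, 0.3])) == 24.0

    def test_tie_breaks_toward_lowest_temperature(self):
        assert lg.find_tm(self.deriv([40, 41], [0.5, 0.5])) == 40.0

    def test_logistic_transition_peaks_at_tm(self, gp_curve_factory):
        curve = logistic_curve(gp_curve_factory, tm=41.0, k=0.4, t_min=31, t_max=51, step=1)
        d = lg.central_difference(curve)
        # oracle: the analytic logistic derivative is maximal at tm, which
        # lies on the grid, so the grid argmax must be exactly tm
        assert lg.find_tm(d, refine=False) == 41.0

    def test_flat_derivative_is_no_transition(self):
        with pytest.raises(NoTransitionError):
            lg.find_tm(self.deriv([1, 2, 3], [0.2, 0.2, 0.2]))

    def test_parabolic_refinement_recovers_vertex(self):
        # samples of y = 1 - (t - 24.4)^2 around its vertex
        t = np.array([23.0, 24.0, 25.0])
        y = 1.0 - (t - 24.4) ** 2
        assert lg.find_tm(self.deriv(t, y), refine=True) == pytest.approx(24.4)

    def test_refinement_clamped_to_neighbor_interval(self):
        t = np.array([23.0, 24.0, 25.0])
        tm = lg.find_tm(self.deriv(t, [0.1, 0.5, 0.49]), refine=True)
        assert 23.0 <= tm <= 25.0


class TestFwhm:
    def test_triangular_peak(self):
        d = lg.DerivativeCurve(
            temperatures_C=np.array([0.0, 1.0, 2.0]),
            neg_dgp_dt=np.array([0.0, 1.0, 0.0]),
        )
        assert lg.fwhm(d) == pytest.approx(1.0)

    @pytest.mark.parametrize("step, rtol", [(1.0, 0.25), (0.1, 0.01), (0.01, 1e-3)])
    def test_logistic_fwhm_converges_to_closed_form(self, gp_curve_factory, step, rtol):
        k = 2.0
        curve = logistic_curve(
            gp_curve_factory, tm=0.0, k=k, t_min=-25, t_max=25, step=step
        )
        width = lg.fwhm(lg.central_difference(curve))
        assert width == pytest.approx(k * LOGISTIC_FWHM_FACTOR, rel=rtol)

    def test_truncated_peak_is_error(self):
        d = lg.DerivativeCurve(
            temperatures_C=np.arange(5.0),
            neg_dgp_dt=np.array([0.1, 0.2, 0.3, 0.4, 0.5]),  # max at range edge
        )
        with pytest.raises(TruncatedPeakError):
            lg.fwhm(d)

    def test_fwhm_increases_with_transition_width(self, gp_curve_factory):
        widths = []
        for k in (0.5, 1.5, 3.0):
            curve = logistic_curve(
                gp_curve_factory, tm=0.0, k=k, t_min=-30, t_max=30, step=0.1
            )
            widths.append(lg.fwhm(lg.central_difference(curve)))
        assert widths[0] < widths[1] < widths[2]


class TestAuc:
    def test_zero_derivative_zero_area(self, gp_curve_factory):
        d = lg.central_difference(gp_curve_factory(np.arange(5.0), np.full(5, 0.2)))
        assert lg.auc(d) == 0.0

    def test_area_equals_gp_drop(self, gp_curve_factory):
        curve = logistic_curve(
            gp_curve_factory, tm=20.0, k=1.0, t_min=0, t_max=40, step=0.5,
            gp_gel=0.5, gp_fluid=-0.1,
        )
        assert lg.auc(lg.central_difference(curve)) == pytest.approx(0.6, rel=0.02)

    def test_logistic_default_plateaus(self, gp_curve_factory):
        # plateaus 0.55 -> -0.15 over tm +/- 10k: drop of 0.70
        curve = logistic_curve(
            gp_curve_factory, tm=0.0, k=1.0, t_min=-10, t_max=10, step=0.25
        )
        assert lg.auc(lg.central_difference(curve)) == pytest.approx(0.70, rel=0.02)

    def test_gp_drop_identity_on_random_smooth_curves(self, rng, gp_curve_factory):
        """AUC approximates GP(first) - GP(last) on smooth random melting
        curves sampled at <= 1 degC, within 2% relative error."""
        for _ in range(20):
            tm = rng.uniform(20, 40)
            k = rng.uniform(0.8, 3.0)
            gel = rng.uniform(0.3, 0.6)
            fluid = rng.uniform(-0.3, 0.0)
            curve = logistic_curve(
                gp_curve_factory, tm=tm, k=k, t_min=tm - 12 * k, t_max=tm + 12 * k,
                step=min(1.0, k / 2), gp_gel=gel, gp_fluid=fluid,
            )
            drop = curve.gp_mean[0] - curve.gp_mean[-1]
            assert lg.auc(lg.central_difference(curve)) == pytest.approx(
                drop, rel=0.02
            )


class TestDetectTransition:
    def test_sharp_peak_on_flat_baseline(self, gp_curve_factory):
        curve = logistic_curve(gp_curve_factory, tm=41, k=0.4, t_min=31, t_max=51, step=1)
        assert lg.detect_transition(lg.central_difference(curve)) is True

    def test_noise_with_edge_maximum_rejected(self):
        vals = np.array([0.5, 0.01, -0.02, 0.015, -0.01])
        d = lg.DerivativeCurve(temperatures_C=np.arange(5.0), neg_dgp_dt=vals)
        assert lg.detect_transition(d) is False

    def test_constant_derivative_rejected(self, gp_curve_factory):
        t = np.arange(10.0)
        d = lg.central_difference(gp_curve_factory(t, -0.02 * t))
        assert lg.detect_transition(d) is False

    def test_zero_derivative_rejected(self, gp_curve_factory):
        d = lg.central_difference(gp_curve_factory(np.arange(5.0), np.full(5, 0.1)))
        assert lg.detect_transition(d) is False


class TestDeltaTm:
    def summary(self, tm, detected=True, sample="s"):
        return lg.MeltingSummary(
            sample_id=sample, lipid="X", assembly="LUV",
            tm_C=tm if detected else None, fwhm_C=None, auc_gp=0.7,
            gp_low=-0.15, gp_high=0.55, transition_detected=detected,
        )

    @pytest.mark.parametrize(
        "tm_sample, tm_ref, expected", [(29.0, 24.0, 5.0), (43.0, 41.0, 2.0), (41.0, 41.0, 0.0)]
    )
    def test_shift_is_sample_minus_reference(self, tm_sample, tm_ref, expected):
        assert lg.delta_tm(self.summary(tm_sample), self.summary(tm_ref)) == expected

    def test_undetected_transition_gives_na_with_warning(self):
        with pytest.warns(UserWarning, match="not detected"):
            assert lg.delta_tm(self.summary(29.0), self.summary(None, detected=False)) is None


class TestAnalyzeCurve:
    def test_full_summary_on_logistic(self, gp_curve_factory):
        curve = logistic_curve(gp_curve_factory, tm=24, k=0.4, t_min=14, t_max=34, step=1)
        s = lg.analyze_curve(curve)
        assert s.transition_detected and s.tm_C == 24.0
        assert s.fwhm_C > 0
        assert s.gp_high == pytest.approx(0.55, abs=1e-6)
        assert s.gp_low == pytest.approx(-0.15, abs=1e-6)
        assert s.auc_gp == pytest.approx(0.70, rel=0.05)

    def test_no_transition_summary_has_none_tm(self, gp_curve_factory):
        t = np.arange(10.0)
        s = lg.analyze_curve(gp_curve_factory(t, 0.3 - 0.002 * t))
        assert not s.transition_detected and s.tm_C is None and s.fwhm_C is None
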