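"""One-compartment (Bateman) model: closed forms, calibration, estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ocupk import (
    BatemanPK,
    ConcProfile,
    IN_VIVO_SAMPLE_TIMES,
    OneCompartmentFit,
    bateman_auc,
    bateman_conc,
    calibrate_from_summary,
    fit_bateman,
    fit_terminal_ke,
    tmax_cmax,
)
from conftest import GCM, SOLUTION


class TestClosedForms:
    def test_concentration_is_zero_at_dose_time(self, gcm_fit):
        assert bateman_conc(gcm_fit, 0.0) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "summary, expected_tmax", [(GCM, 2.944), (SOLUTION, 1.816)]
    )
    def test_peak_time_matches_grid_maximisation(self, summary, expected_tmax):
        fit = calibrate_from_summary(summary["ka"], summary["ke"], summary["cmax"])
        grid = np.arange(0.0, 12.0, 0.001)
        t_grid = grid[np.argmax(bateman_conc(fit, grid))]
        assert fit.tmax == pytest.approx(expected_tmax, abs=2e-3)
        assert abs(fit.tmax - t_grid) <= 0.001

    def test_tmax_closed_form_simple_ratio(self):
        tm, _ = tmax_cmax(ka=2.0, ke=1.0, amplitude=1.0)
        assert tm == pytest.approx(math.log(2.0))

    def test_amplitude_scales_cmax_not_tmax(self):
        t1, c1 = tmax_cmax(0.7, 0.1, 10.0)
        t2, c2 = tmax_cmax(0.7, 0.1, 100.0)
        assert t1 == pytest.approx(t2) and c2 == pytest.approx(10 * c1)

    def test_half_life_identity(self, gcm_fit):
        assert gcm_fit.t_half * gcm_fit.ke == pytest.approx(math.log(2.0))

    def test_degenerate_equal_rates_limit(self):
        fit = OneCompartmentFit(ka=0.5, ke=0.5, amplitude=10.0)
        assert fit.degenerate and fit.tmax == pytest.approx(2.0)
        # the limiting curve peaks at 1/ke with value A/e
        assert bateman_conc(fit, fit.tmax) == pytest.approx(10.0 / math.e)

    @given(
        st.floats(0.05, 2.0),
        st.floats(math.log(1.01), math.log(100.0)),
    )
    @settings(max_examples=50, deadline=None)
    def test_closed_form_peak_agrees_with_grid_everywhere(self, ke, log_ratio):
        ka = ke * math.exp(log_ratio)
        fit = OneCompartmentFit(ka=ka, ke=ke, amplitude=1.0)
        grid = np.arange(0.0, fit.tmax * 3 + 1.0, 1e-3)
        t_grid = grid[np.argmax(bateman_conc(fit, grid))]
        assert abs(fit.tmax - t_grid) <= 1e-3


class TestCalibrateFromSummary:
    @pytest.mark.parametrize(
        "summary, expected_a", [(GCM, 88.73), (SOLUTION, 29.44)]
    )
    def test_amplitude_reproduces_printed_cmax(self, summary, expected_a):
        fit = calibrate_from_summary(summary["ka"], summary["ke"], summary["cmax"])
        assert fit.amplitude == pytest.approx(expected_a, abs=0.01)
        # peak of the reconstructed curve equals Cmax to machine precision
        assert fit.cmax == pytest.approx(summary["cmax"], rel=1e-12)

    def test_zero_cmax_gives_zero_amplitude(self):
        assert calibrate_from_summary(0.7, 0.1, 0.0).amplitude == 0.0

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError):
            calibrate_from_summary(-0.7, 0.1, 50.0)


class TestTerminalSlope:
    def test_exact_monoexponential_recovered(self):
        t = np.array([6.0, 12.0, 24.0])
        prof = ConcProfile(t, 10 * np.exp(-0.1233 * t))
        ke, r2, n = fit_terminal_ke(prof, 3)
        assert ke == pytest.approx(0.1233, rel=1e-12)
        assert r2 == pytest.approx(1.0) and n == 3

    def test_rising_tail_flagged_as_non_terminal(self):
        prof = ConcProfile([6.0, 12.0, 24.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="non-terminal"):
            fit_terminal_ke(prof)

    def test_absorption_residue_bias_is_small_on_late_window(self, gcm_fit):
        # noiseless Bateman samples at 12 and 24 h: remaining absorption
        # makes the slope a biased Ke estimate, but only slightly
        t = np.array([12.0, 24.0])
        prof = ConcProfile(t, np.asarray(bateman_conc(gcm_fit, t)))
        ke, _, _ = fit_terminal_ke(prof, 2)
        assert ke == pytest.approx(GCM["ke"], rel=0.02)


class TestBatemanFit:
    def test_noiseless_selfconsistency(self, gcm_fit):
        t = np.array(IN_VIVO_SAMPLE_TIMES)
        prof = ConcProfile(t, np.asarray(bateman_conc(gcm_fit, t)))
        est = fit_bateman(prof)
        assert est.ka == pytest.approx(gcm_fit.ka, rel=1e-3)
        assert est.ke == pytest.approx(gcm_fit.ke, rel=1e-3)
        assert est.amplitude == pytest.approx(gcm_fit.amplitude, rel=1e-3)
        assert not est.flip_flop

    def test_single_nonzero_point_rejected(self):
        with pytest.raises(ValueError):
            fit_bateman(ConcProfile([1.0, 2.0, 3.0], [0.0, 5.0, 0.0]))
        with pytest.raises(ValueError, match="all-zero"):
            BatemanPK().fit([1.0, 2, 3, 4], [0.0, 0, 0, 0])

    def test_flip_flop_flagged_not_swapped(self):
        # a user asserting absorption-limited kinetics may label the slower
        # exponent Ka; the record flags the regime instead of reordering it
        assert OneCompartmentFit(ka=0.08, ke=0.4, amplitude=1.0).flip_flop
        # fitting itself labels the faster exponent Ka (exchangeable
        # exponents make the labels a convention, not an estimate)
        t = np.array(IN_VIVO_SAMPLE_TIMES)
        gen = OneCompartmentFit(ka=0.4, ke=0.08, amplitude=50.0)
        prof = ConcProfile(t, np.asarray(bateman_conc(gen, t)))
        est = fit_bateman(prof)
        assert not est.flip_flop

    def test_estimator_api(self, gcm_fit):
        from sklearn.base import clone

        t = np.array(IN_VIVO_SAMPLE_TIMES)
        c = np.asarray(bateman_conc(gcm_fit, t))
        est = BatemanPK(n_terminal=3)
        assert clone(est).get_params() == {"n_terminal": 3}
        est.fit(t.reshape(-1, 1), c)
        assert est.cmax_ == pytest.approx(GCM["cmax"], rel=1e-3)
        assert est.tmax_ == pytest.approx(2.944, abs=2e-3)
        assert np.allclose(est.predict(t), c, rtol=1e-6)


def test_analytic_auc_matches_numeric_integration(gcm_fit):
    analytic = bateman_auc(gcm_fit, 0.0, 24.0)
    grid = np.linspace(0.0, 24.0, 200_001)
    numeric = np.trapezoid(bateman_conc(gcm_fit, grid), grid)
    assert numeric == pytest.approx(analytic, rel=1e-8)
    # and AUC to infinity approaches A (1/Ke - 1/Ka)
    assert gcm_fit.auc_inf == pytest.approx(
        gcm_fit.amplitude * (1 / gcm_fit.ke - 1 / gcm_fit.ka)
    )
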