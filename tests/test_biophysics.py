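"""Equivalent-circuit inversion, Boltzmann forms and fits."""

import math

import numpy as np
import pytest

from ieephys.biophysics import (BoltzmannParams, boltzmann_charge,
                                boltzmann_nlc, cell_surface_area,
                                fit_capacitance_boltzmann,
                                fit_charge_boltzmann, forward_admittance,
                                iv_analysis, peak_nlc,
                                series_resistance_divider, solve_two_sine)
from ieephys.errors import EstimationError, FitError

P = BoltzmannParams(Qmax=2.5e-12, Vpk=-40e-3, alpha=30.0)  # 0.030 /mV
W1, W2 = 2 * math.pi * 390.6, 2 * math.pi * 781.2


class TestBoltzmannForms:
    def test_charge_midpoint_and_limits(self):
        assert boltzmann_charge(P.Vpk, P) == pytest.approx(P.Qmax / 2)
        assert boltzmann_charge(5.0, P) == pytest.approx(P.Qmax)
        assert boltzmann_charge(-5.0, P) == pytest.approx(0.0, abs=1e-30)

    def test_charge_value_at_zero(self):
        # direct evaluation: 2.5 pC / (1 + e^-1.2)
        expected = 2.5e-12 / (1 + math.exp(-1.2))
        assert boltzmann_charge(0.0, P) == pytest.approx(expected,
                                                         rel=1e-12)

    def test_charge_monotone_increasing(self):
        v = np.linspace(-0.3, 0.3, 200)
        q = boltzmann_charge(v, P)
        assert np.all(np.diff(q) > 0)
        assert np.all((q > 0) & (q < P.Qmax))

    def test_nlc_peak_value_and_location(self):
        assert boltzmann_nlc(P.Vpk, P) == pytest.approx(P.Qmax * P.alpha / 4)
        assert peak_nlc(P) == pytest.approx(18.75e-12)

    def test_nlc_value_at_zero_matches_finite_difference(self):
        h = 1e-7
        fd = (boltzmann_charge(h, P) - boltzmann_charge(-h, P)) / (2 * h)
        assert boltzmann_nlc(0.0, P) == pytest.approx(fd, rel=1e-6)
        assert boltzmann_nlc(0.0, P) == pytest.approx(13.34e-12, rel=1e-3)

    def test_nlc_symmetric_about_vpk(self):
        for delta in (0.001, 0.01, 0.05, 0.2):
            assert boltzmann_nlc(P.Vpk + delta, P) == pytest.approx(
                boltzmann_nlc(P.Vpk - delta, P), rel=1e-12)

    def test_nlc_equals_charge_derivative_on_grid(self):
        v = np.linspace(-0.15, 0.1, 501)
        h = 1e-6
        fd = (boltzmann_charge(v + h, P) - boltzmann_charge(v - h, P)) \
            / (2 * h)
        assert np.allclose(boltzmann_nlc(v, P), fd, rtol=1e-6)

    def test_peak_nlc_equals_grid_max(self):
        v = np.linspace(-0.2, 0.1, 20001)
        assert peak_nlc(P) == pytest.approx(np.max(boltzmann_nlc(v, P)),
                                            rel=1e-7)

    def test_peak_nlc_scalings(self):
        doubled = BoltzmannParams(2 * P.Qmax, P.Vpk, P.alpha)
        assert peak_nlc(doubled) == pytest.approx(2 * peak_nlc(P))
        tiny = BoltzmannParams(P.Qmax, P.Vpk, 1e-9)
        assert peak_nlc(tiny) < 1e-20


class TestForwardAdmittance:
    def test_dc_limit_is_resistive_chain(self):
        y = forward_admittance(0.0, 10e6, 300e6, 20e-12)
        assert y == pytest.approx(1 / 310e6)
        assert y.imag == 0

    def test_printed_example_values(self):
        y = forward_admittance(W1, 10e6, 300e6, 20e-12)
        assert y.real == pytest.approx(21.0e-9, rel=5e-3)
        assert y.imag == pytest.approx(37.5e-9, rel=5e-3)

    def test_susceptance_positive_for_finite_frequency(self):
        for f in (1.0, 100.0, 1e4, 1e7):
            y = forward_admittance(2 * math.pi * f, 10e6, 300e6, 20e-12)
            assert y.imag > 0

    def test_high_frequency_tends_to_series_conductance(self):
        y = forward_admittance(1e12, 10e6, 300e6, 20e-12)
        assert y.real == pytest.approx(1 / 10e6, rel=1e-4)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            forward_admittance(W1, -1.0, 300e6, 20e-12)


class TestTwoSineInversion:
    def test_noise_free_round_trip(self):
        Rs, Rm, Cm = 10e6, 300e6, 20e-12
        sol = solve_two_sine(forward_admittance(W1, Rs, Rm, Cm),
                             forward_admittance(W2, Rs, Rm, Cm), W1, W2)
        assert sol.Rs_hat == pytest.approx(Rs, rel=1e-8)
        assert sol.Rm_hat == pytest.approx(Rm, rel=1e-8)
        assert sol.Cm_f1 == pytest.approx(Cm, rel=1e-8)
        assert sol.Cm_f2 == pytest.approx(Cm, rel=1e-8)
        assert sol.reported in ("f1", "f2")
        assert sol.Cm_reported == pytest.approx(Cm, rel=1e-8)

    def test_randomised_round_trip_sweep(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            Rs = rng.uniform(5e6, 15e6)
            Rm = rng.uniform(100e6, 500e6)
            Cm = rng.uniform(15e-12, 40e-12)
            sol = solve_two_sine(forward_admittance(W1, Rs, Rm, Cm),
                                 forward_admittance(W2, Rs, Rm, Cm),
                                 W1, W2)
            for got, want in ((sol.Rs_hat, Rs), (sol.Rm_hat, Rm),
                              (sol.Cm_f1, Cm), (sol.Cm_f2, Cm)):
                assert abs(got - want) / want < 1e-8

    def test_monte_carlo_capacitance_error_under_noise(self):
        """1% multiplicative complex noise, 200 replicates: median
        relative capacitance error stays below 5%."""
        rng = np.random.default_rng(21)
        Rs, Rm, Cm = 10e6, 300e6, 20e-12
        y1 = forward_admittance(W1, Rs, Rm, Cm)
        y2 = forward_admittance(W2, Rs, Rm, Cm)
        errs = []
        for _ in range(200):
            n1 = 1 + rng.normal(0, 0.01) + 1j * rng.normal(0, 0.01)
            n2 = 1 + rng.normal(0, 0.01) + 1j * rng.normal(0, 0.01)
            try:
                sol = solve_two_sine(y1 * n1, y2 * n2, W1, W2)
            except EstimationError:
                continue
            errs.append(abs(sol.Cm_reported - Cm) / Cm)
        assert len(errs) > 150
        assert np.median(errs) < 0.05

    def test_degenerate_pure_resistor(self):
        y = forward_admittance(W1, 10e6, 300e6, 0.0)
        with pytest.raises(EstimationError):
            solve_two_sine(y, y, W1, W2)

    def test_forced_report_flag(self):
        Rs, Rm, Cm = 10e6, 300e6, 20e-12
        sol = solve_two_sine(forward_admittance(W1, Rs, Rm, Cm),
                             forward_admittance(W2, Rs, Rm, Cm),
                             W1, W2, report="f2")
        assert sol.reported == "f2"


class TestDividerAndIV:
    def test_divider_values(self):
        assert series_resistance_divider(-60e-3, 10e6, 300e6) == \
            pytest.approx(-58.06e-3, rel=1e-3)
        assert series_resistance_divider(-60e-3, 0.0, 300e6) == -60e-3
        assert series_resistance_divider(-60e-3, 300e6, 300e6) == \
            pytest.approx(-30e-3)

    @staticmethod
    def _ohmic_steps(Rs, Rm, n=1000):
        Vc = np.arange(-100, 101, 20) * 1e-3
        I_ss = Vc / (Rs + Rm)
        return [(v, np.full(n, i)) for v, i in zip(Vc, I_ss)]

    def test_ohmic_cell_recovers_rm_exactly(self):
        Rs, Rm = 10e6, 300e6
        res = iv_analysis(self._ohmic_steps(Rs, Rm), window=0.5, Rs=Rs)
        assert res.Rb == pytest.approx(Rm, rel=1e-10)
        assert np.all(np.diff(res.Vm) > 0)

    def test_current_scaling_halves_rb(self):
        Rs, Rm = 10e6, 300e6
        steps = self._ohmic_steps(Rs, Rm)
        doubled = [(v, 2 * tr) for v, tr in steps]
        res1 = iv_analysis(steps, Rs=0.0)
        res2 = iv_analysis(doubled, Rs=0.0)
        assert res2.Rb == pytest.approx(res1.Rb / 2, rel=1e-10)

    def test_steady_state_current_value(self):
        # Vc/(Rs+Rm) at -100 mV with 10+300 megaohm
        steps = self._ohmic_steps(10e6, 300e6)
        res = iv_analysis(steps, Rs=10e6)
        assert res.I_mean[0] == pytest.approx(-0.3226e-9, rel=1e-3)

    def test_too_few_steps_rejected(self):
        steps = self._ohmic_steps(10e6, 300e6)[:2]
        with pytest.raises(ValueError):
            iv_analysis(steps)

    def test_zero_spread_rejected(self):
        steps = [(0.0, np.zeros(10))] * 5
        with pytest.raises(EstimationError):
            iv_analysis(steps)


class TestBoltzmannFits:
    V = np.arange(-150, 101, 5) * 1e-3
    CLIN = 18e-12

    def test_capacitance_fit_noise_free_recovery(self):
        cm = self.CLIN + boltzmann_nlc(self.V, P)
        params, clin, diags = fit_capacitance_boltzmann(self.V, cm)
        assert params.Qmax == pytest.approx(P.Qmax, rel=1e-3)
        assert params.Vpk == pytest.approx(P.Vpk, abs=1e-3 * abs(P.Vpk))
        assert params.alpha == pytest.approx(P.alpha, rel=1e-3)
        assert clin == pytest.approx(self.CLIN, rel=1e-3)
        assert diags.converged and not diags.peak_at_boundary

    def test_capacitance_fit_monte_carlo_vpk(self):
        """0.2 pF additive noise over many seeds: Vpk located to < 2 mV."""
        cm0 = self.CLIN + boltzmann_nlc(self.V, P)
        rng = np.random.default_rng(31)
        errs = []
        for _ in range(300):
            cm = cm0 + rng.normal(0, 0.2e-12, cm0.shape)
            try:
                params, _, _ = fit_capacitance_boltzmann(self.V, cm)
            except FitError:
                continue
            errs.append(abs(params.Vpk - P.Vpk))
        assert len(errs) > 250
        assert np.median(errs) < 2e-3

    def test_flat_capacitance_rejected(self):
        with pytest.raises(FitError):
            fit_capacitance_boltzmann(self.V, np.full_like(self.V, 20e-12))

    def test_charge_fit_noise_free_recovery(self):
        q = 0.1e-12 + boltzmann_charge(self.V, P)
        params, offset, diags = fit_charge_boltzmann(self.V, q)
        assert params.Qmax == pytest.approx(P.Qmax, rel=1e-3)
        assert params.Vpk == pytest.approx(P.Vpk, abs=4e-5)
        assert params.alpha == pytest.approx(P.alpha, rel=1e-3)
        assert offset == pytest.approx(0.1e-12, rel=1e-3)
        assert diags.converged

    def test_constant_charge_rejected(self):
        with pytest.raises(FitError):
            fit_charge_boltzmann(self.V, np.full_like(self.V, 1e-12))

    def test_charge_and_capacitance_forms_agree(self):
        """Fitting Q(V) and its derivative Cnl(V) for the same cell must
        land on the same (Qmax, Vpk, alpha)."""
        q = boltzmann_charge(self.V, P)
        cm = self.CLIN + boltzmann_nlc(self.V, P)
        pq, _, _ = fit_charge_boltzmann(self.V, q)
        pc, _, _ = fit_capacitance_boltzmann(self.V, cm)
        assert abs(pq.Vpk - pc.Vpk) < 1e-4      # < 0.1 mV
        assert pq.Qmax == pytest.approx(pc.Qmax, rel=2e-3)
        assert pq.alpha == pytest.approx(pc.alpha, rel=2e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_capacitance_boltzmann(self.V[:5],
                                      self.CLIN + boltzmann_nlc(self.V[:5],
                                                                P))


class TestSurfaceArea:
    def test_lateral_cylinder_value(self):
        assert cell_surface_area(60.0, 9.0) == \
            pytest.approx(math.pi * 9 * 60)

    def test_linearity_in_length(self):
        assert cell_surface_area(120.0, 9.0) == \
            pytest.approx(2 * cell_surface_area(60.0, 9.0))

    def test_caps_option(self):
        extra = cell_surface_area(60.0, 9.0, include_caps=True) - \
            cell_surface_area(60.0, 9.0)
        assert extra == pytest.approx(math.pi * 81 / 2)

    @pytest.mark.parametrize("length,diam", [(0, 9), (60, 0), (-1, 9)])
    def test_domain_errors(self, length, diam):
        with pytest.raises(ValueError):
            cell_surface_area(length, diam)
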