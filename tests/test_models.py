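"""Response functions of the generalized fractional model and its sub-models."""

import json
import math

import numpy as np
import pytest

from conftest import random_params
from helpers import sls_closed_forms
from rheofract import (
    FractionalModelParams,
    SpectrumError,
    characteristic_times,
    complex_modulus,
    creep_compliance,
    laplace_creep,
    laplace_relaxation,
    master_curve_transform,
    relaxation_modulus,
    relaxation_spectrum,
)


class TestParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            FractionalModelParams(c_beta=-1.0, beta=0.3)
        with pytest.raises(ValueError):
            FractionalModelParams(c_beta=1.0, beta=1.0)  # dashpot-degenerate
        with pytest.raises(ValueError):
            FractionalModelParams(c_beta=1.0, beta=0.3, eta=0.0)
        with pytest.raises(ValueError):
            FractionalModelParams(c_beta=1.0, beta=0.3, k=-2.0)

    def test_json_round_trip_encodes_missing_dashpot_as_null(self):
        p = FractionalModelParams.fractional_kelvin_voigt(100.0, 0.4, 20.0)
        doc = json.loads(p.to_json())
        assert doc["eta"] is None
        assert FractionalModelParams.from_json(p.to_json()) == p


class TestRelaxationModulus:
    def test_sls_closed_form_value(self):
        # c e^{-ct/eta} + k at c=eta=k=1, t=1: 1 + 1/e
        p = FractionalModelParams.standard_linear_solid(1.0, 1.0, 1.0)
        assert relaxation_modulus(p, 1.0) == pytest.approx(1.0 + math.exp(-1.0), rel=1e-12)

    def test_high_precision_fractional_value(self):
        # frozen from a 50-digit arbitrary-precision series evaluation
        p = FractionalModelParams(c_beta=2.0, beta=0.3, eta=5.0, k=1.0)
        assert relaxation_modulus(p, 0.7) == pytest.approx(2.1049443714669142, rel=1e-12)

    def test_plateau_is_spring_stiffness(self, full_model):
        g = relaxation_modulus(full_model, 1e6 * full_model.tau1)
        assert g == pytest.approx(full_model.k, rel=1e-2)

    def test_monotone_nonincreasing(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            p = random_params(rng)
            t = np.logspace(-3, 3, 200) * p.tau1
            assert np.all(np.diff(relaxation_modulus(p, t)) <= 1e-12)

    def test_short_time_power_law_slope(self):
        """Fitted log-log slope of G - k approaches -beta; on the window
        [1e-4, 1e-2] tau1 it is within 0.01 for moderate beta, and the
        deviation shrinks as the window moves to shorter times."""
        for beta in (0.1, 0.2, 0.25):
            p = FractionalModelParams(c_beta=200.0, beta=beta, eta=1000.0, k=100.0)
            t = np.logspace(-4, -2, 30) * p.tau1
            slope = np.polyfit(np.log(t), np.log(relaxation_modulus(p, t) - p.k), 1)[0]
            assert slope == pytest.approx(-beta, abs=0.01)
        p = FractionalModelParams(c_beta=200.0, beta=0.5, eta=1000.0, k=100.0)
        devs = []
        for lo in (-3.0, -5.0, -7.0):
            t = np.logspace(lo, lo + 2.0, 30) * p.tau1
            s = np.polyfit(np.log(t), np.log(relaxation_modulus(p, t) - p.k), 1)[0]
            devs.append(abs(s + 0.5))
        assert devs[0] > devs[1] > devs[2]
        assert devs[2] < 2e-3

    def test_fmm_accelerated_decay_beyond_tau1(self, fmm_model):
        """Past tau1 the FMM relaxation accelerates far beyond the initial
        power law: the local log-log slope steepens monotonically from -beta
        through a minimum below -(2 - beta), before the far algebraic tail
        t^-(2-beta) of the Mittag-Leffler kernel takes over."""
        beta, tau1 = fmm_model.beta, fmm_model.tau1
        t = np.logspace(-3, 4, 100) * tau1
        g = relaxation_modulus(fmm_model, t)
        slopes = np.diff(np.log(g)) / np.diff(np.log(t))
        i_min = int(np.argmin(slopes))
        assert np.all(np.diff(slopes[: i_min + 1]) < 0)  # monotone steepening
        assert slopes[0] == pytest.approx(-beta, abs=0.05)
        assert slopes[i_min] < -(2.0 - beta) - 0.05  # overshoot past the tail slope
        assert slopes[-1] == pytest.approx(-(2.0 - beta), abs=0.02)  # algebraic tail

    def test_rejects_nonpositive_time(self, full_model):
        with pytest.raises(ValueError):
            relaxation_modulus(full_model, 0.0)


class TestLaplaceDomain:
    def test_sls_transform_value(self):
        p = FractionalModelParams.standard_linear_solid(1.0, 1.0, 1.0)
        assert laplace_relaxation(p, 1.0) == pytest.approx(1.5, rel=1e-12)

    def test_reciprocity_product_over_six_decades(self):
        """G~(s) J~(s) s^2 = 1 for 20 random parameter draws."""
        rng = np.random.default_rng(7)
        s = np.logspace(-3, 3, 25)
        for _ in range(20):
            p = random_params(rng)
            prod = laplace_relaxation(p, s) * laplace_creep(p, s) * s * s
            np.testing.assert_allclose(prod, 1.0, rtol=1e-8)

    def test_matches_quadrature_of_relaxation_modulus(self):
        """G~(s) equals the defining integral of e^{-st} G(t) numerically."""
        from scipy.integrate import quad

        p = FractionalModelParams(c_beta=2.0, beta=0.3, eta=5.0, k=1.0)
        s0 = 10.0
        # remove the t^-beta singularity with the substitution t = w^(1/(1-b))
        a = 1.0 - p.beta
        f = lambda w: float(
            relaxation_modulus(p, max(w, 1e-300) ** (1.0 / a))
            * math.exp(-s0 * w ** (1.0 / a))
            * (1.0 / a)
            * w ** (1.0 / a - 1.0)
        )
        val, _ = quad(f, 0.0, 8.0, epsabs=1e-13, epsrel=1e-10, limit=300)
        assert laplace_relaxation(p, s0) == pytest.approx(val, rel=1e-6)

    def test_frequency_limits(self, full_model):
        p = full_model
        s = np.array([1e-8, 1e8])
        sg = s * laplace_relaxation(p, s)
        assert sg[0] == pytest.approx(p.k, rel=1e-3)
        assert sg[1] - p.k == pytest.approx(p.c_beta * s[1] ** p.beta, rel=1e-4)


class TestCreepCompliance:
    def test_long_time_plateau_is_inverse_stiffness(self, full_model):
        t = 1e6 * max(full_model.tau1, full_model.eta / full_model.k)
        assert creep_compliance(full_model, np.array([t]))[0] == pytest.approx(
            1.0 / full_model.k, rel=1e-2
        )

    def test_spring_pot_fractional_step_response(self):
        # J(t) = t^b / (c Gamma(1+b)); at b=1/2, c=1, t=1: 1/Gamma(1.5)
        p = FractionalModelParams.spring_pot(1.0, 0.5)
        assert creep_compliance(p, np.array([1.0]))[0] == pytest.approx(
            1.0 / math.gamma(1.5), rel=1e-12
        )

    def test_sls_closed_form(self):
        p = FractionalModelParams.standard_linear_solid(1.0, 1.0, 1.0)
        _, J, _, _ = sls_closed_forms(1.0, 1.0, 1.0)
        t = np.logspace(-2, 2, 20)
        np.testing.assert_allclose(creep_compliance(p, t), J(t), rtol=1e-12)

    def test_monotone_nondecreasing(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            p = random_params(rng)
            t = np.logspace(-3, 3, 150) * max(p.tau1, p.eta / p.k)
            assert np.all(np.diff(creep_compliance(p, t)) >= -1e-14)

    def test_starts_from_zero_for_fractional_exponent(self, full_model):
        j = creep_compliance(full_model, np.array([0.0, 1e-12]))
        assert j[0] == 0.0
        assert j[1] < 1e-3 / full_model.k

    def test_fluid_when_spring_absent(self, fmm_model):
        t = np.array([1e7]) * fmm_model.tau1
        j = creep_compliance(fmm_model, t)
        assert j[0] == pytest.approx(t[0] / fmm_model.eta, rel=1e-3)  # unbounded flow


class TestComplexModulus:
    def test_sls_values(self):
        p = FractionalModelParams.standard_linear_solid(1.0, 1.0, 1.0)
        gp, gpp = complex_modulus(p, np.array([1.0]))
        assert gp[0] == pytest.approx(1.5, rel=1e-12)
        assert gpp[0] == pytest.approx(0.5, rel=1e-12)

    def test_spring_pot_constant_loss_tangent(self, spring_pot_model):
        """The lone spring-pot has frequency-independent phase beta*pi/2."""
        w = np.logspace(-3, 3, 13)
        gp, gpp = complex_modulus(spring_pot_model, w)
        expected = 1.0 / math.tan(spring_pot_model.beta * math.pi / 2.0)
        np.testing.assert_allclose(gp / gpp, expected, rtol=1e-12)

    def test_matches_laplace_transform_continuation(self, full_model):
        """G*(omega) = s G~(s) at s = i omega (analytic continuation)."""
        for w in (0.004, 0.4, 40.0):
            s = np.array([1j * w])
            ref = (s * laplace_relaxation(full_model, s))[0]
            gp, gpp = complex_modulus(full_model, np.array([w]))
            assert gp[0] == pytest.approx(ref.real, rel=1e-8)
            assert gpp[0] == pytest.approx(ref.imag, rel=1e-8)

    def test_limits_and_positivity(self, full_model):
        w = np.logspace(-6, 6, 25)
        gp, gpp = complex_modulus(full_model, w)
        assert np.all(gp >= 0) and np.all(gpp >= 0)
        assert gp[0] == pytest.approx(full_model.k, rel=1e-3)
        # high-frequency log-log slope of the branch modulus |G* - k| is beta
        hi = slice(-5, None)
        branch = np.hypot(gp - full_model.k, gpp)
        slope = np.polyfit(np.log(w[hi]), np.log(branch[hi]), 1)[0]
        assert slope == pytest.approx(full_model.beta, abs=1e-3)


class TestCharacteristicTimes:
    def test_worked_example_dissipative_first(self):
        p = FractionalModelParams(c_beta=1.0, beta=0.4, eta=1.0, k=0.5)
        ts = characteristic_times(p)
        assert ts.tau1 == pytest.approx(1.0)
        assert ts.tau2 == pytest.approx(2.0)
        assert ts.xi == pytest.approx(0.5)
        assert ts.regime == "dissipative-first"

    def test_worked_example_spring_first(self):
        p = FractionalModelParams(c_beta=1.0, beta=0.5, eta=4.0, k=1.0)
        ts = characteristic_times(p)
        assert ts.tau1 == pytest.approx(16.0)
        assert ts.tau2 == pytest.approx(4.0)
        assert ts.xi == pytest.approx(4.0)
        assert ts.regime == "spring-first"

    def test_simultaneous_band(self):
        p = FractionalModelParams(c_beta=200.0, beta=0.3, eta=1000.0, k=105.0)
        assert characteristic_times(p).regime == "simultaneous"

    def test_tau2_prime_identity(self):
        """tau2' = tau1^((b-1)/b) tau2^(1/b) whenever both sides exist."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            p = random_params(rng)
            ts = characteristic_times(p)
            expected = ts.tau1 ** ((p.beta - 1.0) / p.beta) * ts.tau2 ** (1.0 / p.beta)
            assert ts.tau2_prime == pytest.approx(expected, rel=1e-10)

    def test_undefined_fields_are_none(self, fmm_model, spring_pot_model):
        ts = characteristic_times(fmm_model)  # k = 0
        assert ts.tau2 is None and ts.xi is None and ts.regime is None
        ts = characteristic_times(spring_pot_model)  # no dashpot either
        assert math.isinf(ts.tau1) and ts.tau2_prime is None
        sls = FractionalModelParams.standard_linear_solid(1.0, 1.0, 1.0)
        assert characteristic_times(sls).tau2_prime is None  # beta = 0


class TestRelaxationSpectrum:
    def test_spring_pot_spectrum_is_pure_power_law(self, spring_pot_model):
        p = spring_pot_model
        tau = np.logspace(-3, 3, 25)
        h = relaxation_spectrum(p, tau)
        expected = p.c_beta / math.pi * math.sin(p.beta * math.pi) * tau ** (-p.beta)
        np.testing.assert_allclose(h, expected, rtol=1e-2)
        assert np.all(h >= 0)

    def test_sls_spectrum_concentrates_at_maxwell_time(self):
        """beta = 0 has a single relaxation time eta/c: the spectrum is a
        narrow peak there whose log-integral recovers the arm stiffness."""
        p = FractionalModelParams.standard_linear_solid(200.0, 1000.0, 100.0)
        tau_m = p.eta / p.c_beta
        tau = np.logspace(math.log10(tau_m) - 3, math.log10(tau_m) + 3, 8001)
        h = relaxation_spectrum(p, tau, angle_offset=1e-2)
        assert tau[np.argmax(h)] == pytest.approx(tau_m, rel=1e-2)
        # full width at half maximum is narrow on the log axis
        above = tau[h > 0.5 * h.max()]
        assert above.max() / above.min() < 1.05
        integral = np.trapezoid(h, np.log(tau))
        assert integral == pytest.approx(p.c_beta, rel=5e-2)

    def test_fmm_quasi_flat_spectrum_with_cutoff(self):
        """A small spring-pot exponent gives the quasi-flat spectrum with
        cut-off at tau1 reported for cortical rheology: H ~ tau^-beta varies
        slowly below tau1 and collapses beyond it."""
        p = FractionalModelParams.fractional_maxwell(100.0, 0.1, 1000.0)
        tau1 = p.tau1
        tau_flat = np.logspace(math.log10(tau1) - 3, math.log10(tau1) - 1, 10)
        h_flat = relaxation_spectrum(p, tau_flat)
        assert h_flat.max() / h_flat.min() < 2.0  # slowly varying below cut-off
        h_beyond = relaxation_spectrum(p, np.array([30.0 * tau1]))
        assert h_beyond[0] < 0.05 * h_flat.mean()  # decayed beyond tau1

    def test_signals_singular_continuation(self):
        p = FractionalModelParams.standard_linear_solid(1.0, 1.0, 1.0)
        with pytest.raises(SpectrumError):
            relaxation_spectrum(p, np.array([1.0]), angle_offset=1e-14)


class TestMasterCurve:
    def test_collapse_at_equal_beta(self):
        """Parameter sets sharing beta map onto one curve in reduced units."""
        x_ref = None
        for fac in (1.0, 10.0):
            p = FractionalModelParams(2.0 * fac, 0.3, 5.0 * fac, 1.0)
            t = np.logspace(-2, 2, 30) * p.tau1
            x, y = master_curve_transform((t, relaxation_modulus(p, t)), p)
            if x_ref is None:
                x_ref, y_ref = x, y
            else:
                np.testing.assert_allclose(x, x_ref, rtol=1e-12)
                np.testing.assert_allclose(y, y_ref, rtol=1e-8)

    def test_plateau_maps_to_zero(self, full_model):
        t = np.array([1e7 * full_model.tau1])
        _, y = master_curve_transform((t, relaxation_modulus(full_model, t)), full_model)
        assert abs(y[0]) < 1e-6

    def test_different_beta_do_not_collapse(self):
        curves = []
        for beta in (0.2, 0.4):
            p = FractionalModelParams(200.0, beta, 1000.0, 100.0)
            t = np.logspace(-2, 2, 30) * p.tau1
            curves.append(master_curve_transform((t, relaxation_modulus(p, t)), p)[1])
        assert np.max(np.abs(curves[0] - curves[1])) > 0.01

    def test_refuses_nonpositive_times(self, full_model):
        with pytest.raises(ValueError):
            master_curve_transform((np.array([0.0, 1.0]), np.array([1.0, 1.0])), full_model)
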