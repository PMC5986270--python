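"""Boltzmann and electrode calibration: fits, inversion, steady states."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from protonflux import (
    BoltzmannParams,
    CalibrationPoint,
    ElectrodeCalibration,
    boltzmann_ratio,
    calibrate_electrode,
    fit_boltzmann,
    ratio_to_ph,
    ratio_trace_to_ph,
    steady_state_fit,
    steady_state_value,
    voltage_to_ph,
)
from protonflux.errors import (
    CalibrationDomainError,
    InsufficientDataError,
    TraceKindError,
    UnidentifiableFitError,
)
from protonflux.synthetic_data import gen_electrode_recording
from protonflux.trace_model import ApplicationProtocol, SolutionEvent

from conftest import make_trace


class TestSteadyState:
    def test_constant_segment_returns_its_value(self):
        tr = make_trace(np.arange(10.0), np.full(10, 1.5), "ratio")
        assert steady_state_value(tr) == pytest.approx(1.5)

    def test_noiseless_exponential_recovers_asymptote(self):
        t = np.arange(0.0, 200.0, 1.0)
        tr = make_trace(t, 1.0 + 0.5 * np.exp(-t / 20.0), "ratio")
        assert steady_state_value(tr) == pytest.approx(1.0, abs=1e-6)

    def test_noisy_asymptote_matches_independent_grid_refit(self):
        rng = np.random.default_rng(11)
        t = np.arange(0.0, 200.0, 1.0)
        y = 1.0 + 0.5 * np.exp(-t / 20.0) + rng.normal(0, 0.01, t.size)
        tr = make_trace(t, y, "ratio")
        value = steady_state_value(tr)
        assert value == pytest.approx(1.0, rel=0.02)
        # oracle: grid of tau initialisations, independent least squares
        best = None
        for tau0 in [1.0, 5.0, 20.0, 80.0, 200.0]:
            try:
                popt, _ = optimize.curve_fit(
                    lambda tt, yss, y0, tau: yss + (y0 - yss) * np.exp(-tt / tau),
                    t, y, p0=(y[-1], y[0], tau0), maxfev=10000,
                )
            except RuntimeError:
                continue
            sse = float(np.sum((popt[0] + (popt[1] - popt[0])
                                * np.exp(-t / popt[2]) - y) ** 2))
            if best is None or sse < best[1]:
                best = (popt[0], sse)
        assert value == pytest.approx(best[0], rel=1e-3)

    def test_time_shift_invariance(self):
        t = np.arange(0.0, 120.0, 2.0)
        y = 0.8 + 0.3 * np.exp(-t / 15.0)
        a = steady_state_value(make_trace(t, y, "ratio"))
        b = steady_state_value(make_trace(t + 512.5, y, "ratio"))
        assert a == pytest.approx(b, abs=1e-10)

    def test_too_few_points_raises(self):
        with pytest.raises(InsufficientDataError):
            steady_state_value(make_trace([0, 1, 2], [1, 1, 1], "ratio"))

    def test_fallback_is_recorded(self):
        # alternating, non-exponential data: fit may or may not converge,
        # but the report always says which route produced the value
        tr = make_trace(np.arange(8.0), [0, 9, 0, 9, 0, 9, 0, 9], "ratio")
        fit = steady_state_fit(tr)
        assert fit.method in ("exponential", "final-quartile-mean")
        assert np.isfinite(fit.value)


class TestBoltzmannForward:
    def test_midpoint_is_mean_of_plateaus(self, bparams):
        assert boltzmann_ratio(bparams.x0, bparams) == pytest.approx(
            (bparams.A1 + bparams.A2) / 2
        )

    def test_asymptotes(self, bparams):
        assert boltzmann_ratio(bparams.x0 - 20 * bparams.dx, bparams) == \
            pytest.approx(bparams.A1, abs=1e-8)
        assert boltzmann_ratio(bparams.x0 + 20 * bparams.dx, bparams) == \
            pytest.approx(bparams.A2, abs=1e-8)

    def test_against_direct_arithmetic(self, bparams):
        # independent arithmetic: (A1-A2)/(1+e) + A2 at pH = x0 + dx
        expected = 0.4 + 1.2 / (1.0 + np.e)
        assert boltzmann_ratio(7.5, bparams) == pytest.approx(expected, rel=1e-12)


class TestBoltzmannInverse:
    def test_midpoint_inverse(self, bparams):
        R = (bparams.A1 + bparams.A2) / 2
        assert ratio_to_ph(R, bparams) == pytest.approx(bparams.x0, abs=1e-12)

    def test_round_trip_identity_over_valid_domain(self, bparams):
        pH = np.linspace(bparams.x0 - 3 * bparams.dx,
                         bparams.x0 + 3 * bparams.dx, 201)
        back = ratio_to_ph(boltzmann_ratio(pH, bparams), bparams)
        np.testing.assert_allclose(back, pH, atol=1e-10)

    def test_boundary_ratio_raises(self, bparams):
        with pytest.raises(CalibrationDomainError):
            ratio_to_ph(bparams.A2, bparams)
        with pytest.raises(CalibrationDomainError):
            ratio_to_ph(bparams.A1 + 0.1, bparams)

    @given(ph=st.floats(min_value=5.8, max_value=8.2))
    @settings(derandomize=True, max_examples=60)
    def test_round_trip_property(self, ph):
        params = BoltzmannParams(A1=1.6, A2=0.4, x0=7.0, dx=0.5)
        assert ratio_to_ph(boltzmann_ratio(ph, params), params) == \
            pytest.approx(ph, abs=1e-10)

    def test_trace_conversion_flags_clamped_samples(self, bparams):
        tr = make_trace([0, 1], [1.0, bparams.A2 + 1e-12], "ratio")
        out = ratio_trace_to_ph(tr, bparams)
        assert out.kind == "pH"
        assert out.meta["clamped_samples"] == [1]
        assert np.isfinite(out.y).all()


class TestFitBoltzmann:
    PHS = (6.0, 6.5, 7.0, 7.5, 8.0)

    def test_exact_model_data_recovered(self, bparams):
        pts = [CalibrationPoint(p, boltzmann_ratio(p, bparams))
               for p in self.PHS]
        fit = fit_boltzmann(pts)
        for name in ("A1", "A2", "x0", "dx"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(bparams, name), rel=1e-6
            )
        assert fit.converged

    def test_noisy_points_within_5pc_and_match_grid_oracle(self, bparams):
        rng = np.random.default_rng(5)
        pts = [
            CalibrationPoint(
                p, boltzmann_ratio(p, bparams) + rng.normal(0, 0.01)
            )
            for p in self.PHS
        ]
        fit = fit_boltzmann(pts)
        for name in ("A1", "A2", "x0", "dx"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(bparams, name), rel=0.05
            )
        # oracle: brute-force least squares over a parameter grid, then a
        # local refinement started from the grid optimum
        x = np.array([p.pH for p in pts])
        y = np.array([p.value for p in pts])

        def sse(q):
            a1, a2, x0, dx = q
            return np.sum(
                ((a1 - a2) / (1 + np.exp((x - x0) / dx)) + a2 - y) ** 2
            )

        grid_best = min(
            ((a1, a2, x0, dx)
             for a1 in np.linspace(1.2, 2.0, 9)
             for a2 in np.linspace(0.1, 0.7, 9)
             for x0 in np.linspace(6.2, 7.8, 9)
             for dx in np.linspace(0.2, 1.0, 9)),
            key=sse,
        )
        refined = optimize.minimize(sse, grid_best, method="Nelder-Mead",
                                    options={"xatol": 1e-10, "fatol": 1e-14})
        fitted = (fit.params.A1, fit.params.A2, fit.params.x0, fit.params.dx)
        np.testing.assert_allclose(fitted, refined.x, rtol=1e-3)

    def test_degenerate_inputs_raise(self):
        flat = [CalibrationPoint(p, 1.0) for p in self.PHS]
        with pytest.raises(UnidentifiableFitError):
            fit_boltzmann(flat)
        with pytest.raises(InsufficientDataError):
            fit_boltzmann([CalibrationPoint(6.0, 1.0),
                           CalibrationPoint(7.0, 0.8),
                           CalibrationPoint(8.0, 0.5)])


class TestElectrode:
    def test_two_point_line_is_exact_interpolant(self):
        cal = calibrate_electrode([CalibrationPoint(7.0, 0.0),
                                   CalibrationPoint(6.4, 30.0)])
        assert cal.slope == pytest.approx(-0.02)
        assert cal.intercept == pytest.approx(7.0)

    def test_collinear_points_fit_exactly(self):
        pts = [CalibrationPoint(7.0 - 0.02 * v, v) for v in (0.0, 10.0, 25.0)]
        cal = calibrate_electrode(pts)
        assert cal.slope == pytest.approx(-0.02, abs=1e-12)
        assert cal.intercept == pytest.approx(7.0, abs=1e-12)

    def test_noisy_fit_matches_closed_form_ols(self):
        rng = np.random.default_rng(3)
        V = np.array([0.0, 10.0, 20.0, 30.0, 40.0])
        pH = 7.0 - 0.02 * V + rng.normal(0, 0.01, V.size)
        cal = calibrate_electrode(
            [CalibrationPoint(p, v) for p, v in zip(pH, V)]
        )
        assert cal.slope == pytest.approx(-0.02, rel=0.03)
        # closed-form OLS oracle
        vc = V - V.mean()
        slope = float(np.dot(vc, pH - pH.mean()) / np.dot(vc, vc))
        assert cal.slope == pytest.approx(slope, rel=1e-12)
        assert cal.intercept == pytest.approx(pH.mean() - slope * V.mean(),
                                              rel=1e-12)

    def test_identical_potentials_rejected(self):
        with pytest.raises(UnidentifiableFitError):
            calibrate_electrode([CalibrationPoint(7.0, 5.0),
                                 CalibrationPoint(6.4, 5.0)])

    def test_voltage_to_ph_affine(self):
        cal = ElectrodeCalibration(slope=-0.02, intercept=7.0)
        tr = make_trace([0, 1, 2], [0.0, 0.0, 0.0], "potential_mV")
        out = voltage_to_ph(tr, cal)
        assert out.kind == "pH"
        np.testing.assert_allclose(out.y, 7.0)
        # affine property: mapping aV+b equals the affine image of mapping V
        V = np.array([1.0, 5.0, -3.0])
        a, b = 2.0, 4.0
        lhs = voltage_to_ph(make_trace([0, 1, 2], a * V + b, "potential_mV"),
                            cal).y
        rhs = a * (voltage_to_ph(make_trace([0, 1, 2], V, "potential_mV"),
                                 cal).y - cal.intercept) + \
            cal.slope * b + cal.intercept
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_kind_mismatch_raises(self):
        cal = ElectrodeCalibration(slope=-0.02, intercept=7.0)
        with pytest.raises(TraceKindError):
            voltage_to_ph(make_trace([0, 1], [7, 7], "pH"), cal)

    def test_generator_ground_truth_recovered_without_noise(self):
        protocol = ApplicationProtocol(
            (SolutionEvent("lactate", 10.0, 60.0, 120.0),)
        )
        trace, gt = gen_electrode_recording(protocol, noise_sd_mV=0.0,
                                            drift_mV_per_min=0.0, seed=9)
        cal = ElectrodeCalibration(**gt.params["electrode"])
        recovered = voltage_to_ph(trace, cal)
        np.testing.assert_allclose(recovered.y, gt.params["true_pH"],
                                   atol=1e-10)
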