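"""Proton concentration, rate extraction, buffering, flux, injection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from protonflux import (
    SolutionSpec,
    buffer_capacity,
    extract_rate,
    hco3_intracellular,
    injection_concentration,
    ph_to_proton,
    proton_flux,
    proton_to_ph,
    round_to_sig_figs,
)
from protonflux.errors import (
    ConfigurationError,
    TraceKindError,
    TraceValidationError,
    UnresolvableBufferingError,
    WindowError,
)
from protonflux.flux_quant import BufferingResult, FluxResult, RateEstimate
from protonflux.synthetic_data import gen_lactate_experiment
from protonflux.trace_model import ApplicationProtocol, SolutionEvent

from conftest import make_trace


def exhaustive_max_slope(segment, window_s):
    """Independent oracle: scan every admissible window with linregress."""
    t, y = segment.t, segment.y
    tol = 1e-9 * max(window_s, 1.0)
    best = None
    for i in range(len(t)):
        if t[i] + window_s > t[-1] + tol:
            break
        j = int(np.searchsorted(t, t[i] + window_s + tol, side="right"))
        if j - i < 3:
            continue
        res = stats.linregress(t[i:j], y[i:j])
        if best is None or abs(res.slope) > abs(best[0]):
            best = (res.slope, i, j)
    return best


class TestPhProton:
    def test_reference_values(self):
        tr = make_trace([0, 1], [7.0, 6.0], "pH")
        out = ph_to_proton(tr)
        assert out.kind == "proton_nM"
        np.testing.assert_allclose(out.y, [100.0, 1000.0], rtol=1e-12)

    def test_monotone_and_bijective(self):
        pH = np.linspace(6.0, 7.8, 50)
        tr = make_trace(np.arange(50.0), pH[::-1], "pH")
        prot = ph_to_proton(tr)
        assert np.all(np.diff(prot.y) > 0)  # falling pH = rising [H+]
        back = proton_to_ph(prot)
        np.testing.assert_allclose(back.y, pH[::-1], atol=1e-12)

    def test_kind_mismatch(self):
        with pytest.raises(TraceKindError):
            ph_to_proton(make_trace([0, 1], [1, 2], "ratio"))


class TestExtractRate:
    def test_exact_line_in_both_modes(self):
        t = np.arange(0.0, 120.0, 1.0)
        tr = make_trace(t, 7.4 - 0.01 * t, "pH")
        for mode in ("max-slope", "fixed-window"):
            r = extract_rate(tr, mode=mode, window_s=30.0)
            assert r.slope == pytest.approx(-0.6, rel=1e-10)
            assert r.units == "pH/min"
            assert r.r2 == pytest.approx(1.0)

    def test_constant_segment_zero_slope_r2_zero(self):
        tr = make_trace(np.arange(60.0), np.full(60, 7.2), "pH")
        r = extract_rate(tr, window_s=30.0)
        assert r.slope == 0.0
        assert r.r2 == 0.0

    def test_window_longer_than_segment_raises(self):
        tr = make_trace(np.arange(10.0), np.arange(10.0), "pH")
        with pytest.raises(WindowError):
            extract_rate(tr, window_s=60.0)

    @pytest.mark.parametrize("noise_sd", [0.0, 0.005])
    def test_max_slope_equals_exhaustive_scan_on_exponential(self, noise_sd):
        rng = np.random.default_rng(17)
        t = np.arange(0.0, 300.0, 1.0)
        y = 7.3 - 0.3 * (1 - np.exp(-t / 60.0)) + rng.normal(0, noise_sd,
                                                             t.size)
        tr = make_trace(t, y, "pH")
        r = extract_rate(tr, mode="max-slope", window_s=30.0)
        slope, i, j = exhaustive_max_slope(tr, 30.0)
        assert r.slope == pytest.approx(slope * 60.0, rel=1e-10)
        assert r.window == (t[i], t[j - 1])

    def test_max_slope_on_irregular_sampling(self):
        rng = np.random.default_rng(23)
        t = np.sort(rng.uniform(0, 200, 150))
        y = np.sin(t / 40.0) + rng.normal(0, 0.01, t.size)
        tr = make_trace(t, y, "pH")
        r = extract_rate(tr, mode="max-slope", window_s=25.0)
        slope, i, j = exhaustive_max_slope(tr, 25.0)
        assert r.slope == pytest.approx(slope * 60.0, rel=1e-10)
        assert r.window == (t[i], t[j - 1])

    def test_tie_broken_by_earliest_window(self):
        # symmetric V shape: two windows with equal |slope|
        t = np.arange(0.0, 21.0)
        y = np.abs(t - 10.0)
        r = extract_rate(make_trace(t, y, "pH"), mode="max-slope",
                         window_s=5.0)
        assert r.window[0] == 0.0


class TestHenderson:
    def test_at_pk_hco3_equals_co2(self, solution):
        assert hco3_intracellular(solution.pK_prime, solution) == \
            pytest.approx(solution.co2_mM, rel=1e-12)

    def test_symmetric_equilibrium(self, solution):
        assert hco3_intracellular(solution.pH_o, solution) == \
            pytest.approx(solution.hco3_mM, rel=1e-12)

    def test_worked_value(self, solution):
        # [CO2] = 10/10^0.9; [HCO3-]_i at pH 7.2 = 10 * 10^(7.2-7.0)
        assert hco3_intracellular(7.2, solution) == \
            pytest.approx(10 * 10 ** 0.2, rel=1e-12)

    def test_missing_pk_raises(self):
        sol = SolutionSpec(pK_prime=None)
        with pytest.raises(ConfigurationError):
            hco3_intracellular(7.0, sol)


class TestBufferCapacity:
    def test_definition(self):
        res = BufferingResult(beta_i=20.0, delta_pH=-0.5, delta_hco3=10.0,
                              pH_start=7.2, pH_end=6.7)
        assert res.delta_hco3 / abs(res.delta_pH) == pytest.approx(res.beta_i)

    def test_guard_on_tiny_shift(self, solution):
        t = np.arange(0.0, 200.0, 1.0)
        tr = make_trace(t, np.full(t.size, 7.2), "pH")
        with pytest.raises(UnresolvableBufferingError):
            buffer_capacity(tr, solution, pulse_start_s=100.0)

    @pytest.mark.parametrize("beta_true", [10.0, 20.0, 40.0])
    def test_synthetic_pulse_recovers_beta_within_5pc(self, solution,
                                                      beta_true):
        protocol = ApplicationProtocol(
            (SolutionEvent("CO2", 5.0, 300.0, 600.0),)
        )
        trace, gt = gen_lactate_experiment(
            protocol, beta_true=beta_true, tau_s=30.0, noise_sd=0.003,
            dt_s=1.0, seed=31,
        )
        res = buffer_capacity(trace.crop(0, 600), solution,
                              pulse_start_s=300.0)
        assert res.beta_i == pytest.approx(beta_true, rel=0.05)
        # closed-form inversion oracle: the generator's steady state obeys
        # hco3_i(pH_end) = beta_true * (pH_start - pH_end)
        ph_end = gt.params["co2_steady_pH"][0]
        assert hco3_intracellular(ph_end, solution) == pytest.approx(
            beta_true * (7.2 - ph_end), rel=1e-6
        )


class TestProtonFlux:
    def test_product_and_invariant(self):
        buf = BufferingResult(beta_i=20.0, delta_pH=-0.5, delta_hco3=10.0,
                              pH_start=7.2, pH_end=6.7)
        flux = proton_flux(RateEstimate(0.01, (0, 30), "application", 1.0,
                                        "fixed-window", "pH/min"), buf)
        assert flux.J_H == pytest.approx(0.2)
        zero = proton_flux(RateEstimate(0.0, (0, 30), "application", 0.0,
                                        "fixed-window", "pH/min"), buf)
        assert zero.J_H == 0.0
        with pytest.raises(TraceValidationError):
            FluxResult(J_H=1.0, rate_pH=0.01, beta_i=20.0)
        with pytest.raises(TraceKindError):
            proton_flux(RateEstimate(1.0, (0, 30), "application", 1.0,
                                     "fixed-window", "nM/min"), buf)


class TestInjection:
    def test_oocyte_worked_example_rounds_to_30(self):
        conc = injection_concentration(27.6, 400.0, 0.35)
        assert conc == pytest.approx(29.24, abs=0.01)
        assert round_to_sig_figs(conc, 1) == 30.0

    def test_fixed_point_and_null_injection(self):
        assert injection_concentration(50.0, 30.0, 0.35) < 30.0
        # injecting at the resident concentration leaves it unchanged:
        # resident 30 mM in 0.35 µl plus 27.6 nl of 30 mM is still 30 mM
        v_inj = 27.6e-3
        resident = (0.35 * 30.0 + v_inj * 30.0) / (0.35 + v_inj)
        assert resident == pytest.approx(30.0)
        assert injection_concentration(0.0, 400.0, 0.35) == 0.0

    def test_nonpositive_free_volume_rejected(self):
        with pytest.raises(TraceValidationError):
            injection_concentration(27.6, 400.0, 0.0)

    @given(v=st.floats(min_value=0.1, max_value=100.0),
           c=st.floats(min_value=1.0, max_value=1000.0))
    @settings(derandomize=True, max_examples=40)
    def test_dilution_never_exceeds_injected_concentration(self, v, c):
        assert injection_concentration(v, c, 0.35) < c
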