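"""Transport rates, buffer capacity and proton flux from pH traces.

The chain implemented here turns a calibrated pH (or proton-concentration)
trace plus a solution-change protocol into the physiological quantities of a
proton-coupled lactate transport experiment:

* ``ph_to_proton`` — pointwise ``[H+] = 10**(-pH) * 1e9`` (nM), so rate
  comparisons are not distorted by the logarithmic pH scale;
* ``extract_rate`` — the maximal (or onset-anchored) linear-regression slope
  during substrate application or withdrawal, reported per minute;
* ``buffer_capacity`` — the intrinsic buffering power β_i (mM per pH unit)
  from the acidification produced by a CO2/HCO3- pulse, via
  Henderson–Hasselbalch with membrane-equilibrated CO2;
* ``proton_flux`` — J_H = (ΔpH/Δt) × β_i in mM/min, the acid-equivalent
  flux across the membrane.

Because the experiments are performed in the nominal absence of CO2/HCO3-
outside the terminal pulse, the CO2-dependent buffering term is omitted and
the pre-pulse intracellular bicarbonate is taken as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .calibration import steady_state_value
from .errors import (
    ConfigurationError,
    InsufficientDataError,
    TraceKindError,
    TraceValidationError,
    UnresolvableBufferingError,
    WindowError,
)
from .trace_model import SolutionSpec, Trace


@dataclass(frozen=True)
class RateEstimate:
    """A fitted slope with its window, direction and fit quality.

    ``slope`` is signed and expressed per minute, in the units of the input
    trace (pH/min for pH traces, nM/min for proton traces).
    """

    slope: float
    window: tuple  # (t_a, t_b) seconds
    direction: str  # "application" | "withdrawal"
    r2: float
    mode: str  # "max-slope" | "fixed-window"
    units: str  # e.g. "pH/min"

    def __post_init__(self) -> None:
        t_a, t_b = self.window
        if not t_a < t_b:
            raise TraceValidationError("rate window must satisfy t_a < t_b")


@dataclass(frozen=True)
class BufferingResult:
    """Intrinsic buffer capacity from a CO2/HCO3- pulse."""

    beta_i: float  # mM per pH unit
    delta_pH: float  # pH units (signed, pulse minus baseline)
    delta_hco3: float  # mM
    pH_start: float
    pH_end: float


@dataclass(frozen=True)
class FluxResult:
    """Proton flux J_H = rate × β_i; the identity is asserted on construction."""

    J_H: float  # mM/min
    rate_pH: float  # pH units/min (magnitude)
    beta_i: float  # mM per pH unit
    direction: str = "application"

    def __post_init__(self) -> None:
        if self.J_H != self.rate_pH * self.beta_i:
            raise TraceValidationError(
                "FluxResult invariant violated: J_H != rate_pH * beta_i"
            )


# ---------------------------------------------------------------------------
# pH <-> [H+]
# ---------------------------------------------------------------------------

def ph_to_proton(trace: Trace) -> Trace:
    """Convert a pH trace to proton concentration in nM.

    ``[H+] = 10**(-pH) * 1e9`` applied to every recorded data point.
    """
    if trace.kind != "pH":
        raise TraceKindError(f"expected a pH trace, got {trace.kind!r}")
    return trace.with_values(10.0 ** (-trace.y) * 1e9, "proton_nM")


def proton_to_ph(trace: Trace) -> Trace:
    """Inverse of :func:`ph_to_proton` (log-conversion back to pH)."""
    if trace.kind != "proton_nM":
        raise TraceKindError(f"expected a proton_nM trace, got {trace.kind!r}")
    return trace.with_values(-np.log10(trace.y * 1e-9), "pH")


# ---------------------------------------------------------------------------
# rate extraction
# ---------------------------------------------------------------------------

def _ols_slope(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form OLS slope (per second) and r^2 of y against t."""
    tc = t - t.mean()
    yc = y - y.mean()
    stt = float(np.dot(tc, tc))
    sty = float(np.dot(tc, yc))
    slope = sty / stt
    syy = float(np.dot(yc, yc))
    if syy == 0.0:
        return slope, 0.0  # flat input: r^2 defined as 0 by convention
    ss_res = syy - slope * sty
    return slope, max(0.0, 1.0 - ss_res / syy)


def extract_rate(
    segment: Trace,
    mode: str = "max-slope",
    window_s: float = 30.0,
    direction: str = "application",
) -> RateEstimate:
    """Linear-regression transport rate over a window of the segment.

    ``fixed-window`` regresses over the first ``window_s`` seconds of the
    segment (anchored at the event edge the caller segmented on).
    ``max-slope`` slides a window of length ``window_s`` one sample at a
    time and returns the slope of maximal magnitude, ties broken by the
    earliest window.  Windows are time-based, so irregular sampling is
    handled; each window must contain at least 3 samples.  The slope is
    reported per minute.
    """
    if mode not in ("max-slope", "fixed-window"):
        raise ValueError(f"unknown mode {mode!r}")
    if direction not in ("application", "withdrawal"):
        raise ValueError(f"unknown direction {direction!r}")
    t, y = segment.t, segment.y
    if segment.duration < window_s:
        raise WindowError(
            f"segment spans {segment.duration:.3g} s, shorter than the "
            f"requested {window_s:.3g} s window"
        )
    tol = 1e-9 * max(window_s, 1.0)

    def window_at(i: int):
        j = int(np.searchsorted(t, t[i] + window_s + tol, side="right"))
        return j

    if mode == "fixed-window":
        j = window_at(0)
        if j - 0 < 3:
            raise InsufficientDataError(
                f"window holds {j} samples; need >= 3"
            )
        slope, r2 = _ols_slope(t[:j], y[:j])
        win = (float(t[0]), float(t[j - 1]))
    else:
        best = None
        for i in range(len(t)):
            if t[i] + window_s > t[-1] + tol:
                break
            j = window_at(i)
            if j - i < 3:
                continue
            slope, r2 = _ols_slope(t[i:j], y[i:j])
            if best is None or abs(slope) > abs(best[0]):
                best = (slope, r2, i, j)
        if best is None:
            raise InsufficientDataError(
                "no admissible window with >= 3 samples"
            )
        slope, r2, i, j = best
        win = (float(t[i]), float(t[j - 1]))

    unit = {
        "pH": "pH/min",
        "proton_nM": "nM/min",
        "ratio": "ratio/min",
        "potential_mV": "mV/min",
        "log_enrichment": "LE/min",
    }[segment.kind]
    return RateEstimate(
        slope=slope * 60.0,
        window=win,
        direction=direction,
        r2=r2,
        mode=mode,
        units=unit,
    )


# ---------------------------------------------------------------------------
# buffering and flux
# ---------------------------------------------------------------------------

def hco3_intracellular(pH_i: float, solution: SolutionSpec) -> float:
    """Intracellular [HCO3-] (mM) assuming membrane-equilibrated CO2.

    The dissolved CO2 set by the extracellular equilibrium,
    ``[CO2] = [HCO3-]_o / 10**(pH_o - pK')``, is combined with the
    intracellular pH through Henderson–Hasselbalch:
    ``[HCO3-]_i = [CO2] * 10**(pH_i - pK')``.
    """
    if solution.pK_prime is None:
        raise ConfigurationError("solution pK' is required for [HCO3-]_i")
    return solution.co2_mM * 10.0 ** (pH_i - solution.pK_prime)


def buffer_capacity(
    segment: Trace,
    solution: SolutionSpec,
    pulse_start_s: float,
    min_delta_pH: float = 0.01,
) -> BufferingResult:
    """Intrinsic buffer capacity β_i from a CO2/HCO3- pulse.

    ``segment`` must cover the pre-pulse baseline and the acidified
    steady state during the pulse; ``pulse_start_s`` marks the solution
    change.  Both plateaus are estimated by mono-exponential regression.
    Because the baseline is nominally CO2/HCO3–free, the pre-pulse
    intracellular bicarbonate is taken as 0 mM and Δ[HCO3-]_i equals the
    pulse steady-state value.  β_i = Δ[HCO3-]_i / |ΔpH_i|.
    """
    if segment.kind != "pH":
        raise TraceKindError(f"expected a pH trace, got {segment.kind!r}")
    pre = segment.crop(segment.t[0], pulse_start_s)
    during = segment.crop(pulse_start_s, segment.t[-1])
    pH_start = steady_state_value(pre)
    pH_end = steady_state_value(during)
    delta_pH = pH_end - pH_start
    if abs(delta_pH) < min_delta_pH:
        raise UnresolvableBufferingError(
            f"|ΔpH| = {abs(delta_pH):.4f} below the {min_delta_pH} "
            "resolution guard"
        )
    delta_hco3 = hco3_intracellular(pH_end, solution)  # baseline ~ 0 mM
    return BufferingResult(
        beta_i=delta_hco3 / abs(delta_pH),
        delta_pH=delta_pH,
        delta_hco3=delta_hco3,
        pH_start=pH_start,
        pH_end=pH_end,
    )


def proton_flux(rate: RateEstimate, buffering: BufferingResult) -> FluxResult:
    """Lactate-induced proton flux J_H = |ΔpH/Δt| × β_i (mM/min).

    The sign of the underlying pH change is carried by the rate's
    ``direction`` metadata; J_H itself is a magnitude.
    """
    if rate.units != "pH/min":
        raise TraceKindError(
            f"proton flux needs a rate in pH/min, got {rate.units!r}"
        )
    mag = abs(rate.slope)
    return FluxResult(
        J_H=mag * buffering.beta_i,
        rate_pH=mag,
        beta_i=buffering.beta_i,
        direction=rate.direction,
    )


# ---------------------------------------------------------------------------
# injection dilution
# ---------------------------------------------------------------------------

def injection_concentration(
    inject_volume_nl: float,
    inject_conc_mM: float,
    free_volume_ul: float = 0.35,
) -> float:
    """Intracellular concentration after injecting a bolus into a cell.

    ``(V_inject × C_inject) / (V_free + V_inject)`` with the injected
    volume in nl and the effective free (accessible) volume in µl.  For an
    oocyte the effective free volume is about 0.35 µl.
    """
    if free_volume_ul <= 0:
        raise TraceValidationError("free volume must be positive")
    if inject_volume_nl < 0 or inject_conc_mM < 0:
        raise TraceValidationError("injection volume/concentration must be >= 0")
    v_inj_ul = inject_volume_nl * 1e-3
    return (v_inj_ul * inject_conc_mM) / (free_volume_ul + v_inj_ul)


def round_to_sig_figs(value: float, n: int = 1) -> float:
    """Reporting helper: round to ``n`` significant figures."""
    if value == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(value)))
    return round(value, -exponent + n - 1)
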