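"""Convert raw ratiometric or electrode signals to pH.

Two calibration routes are implemented:

* **Ratiometric dye (SNARF-type).**  During a nigericin clamp the cell is
  superfused with salines of known pH; the steady-state emission ratio at
  each step is fitted with a Boltzmann sigmoid

  .. math:: R(\\mathrm{pH}) = \\frac{A_1 - A_2}{1 + e^{(\\mathrm{pH}-x_0)/dx}} + A_2

  whose algebraic inverse
  ``pH = x0 + dx * ln((A1 - A2)/(R - A2) - 1)`` converts every recorded
  ratio to pH.  ``A1``/``A2`` are the acidic/alkaline plateaus, ``x0`` the
  midpoint (close to the dye's pK_a) and ``dx`` the sigmoid width in pH
  units.

* **Ion-sensitive microelectrode.**  The electrode potential is recorded in
  two (or more) calibration salines of known pH and the line
  ``pH = intercept + slope * V_e`` is fitted by ordinary least squares;
  recorded potentials are then mapped point-wise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .errors import (
    CalibrationDomainError,
    InsufficientDataError,
    TraceKindError,
    UnidentifiableFitError,
)
from .trace_model import Trace


@dataclass(frozen=True)
class BoltzmannParams:
    """Parameters of the ratio-vs-pH calibration sigmoid.

    ``A1`` is the low-pH (acidic) plateau, ``A2`` the high-pH plateau,
    ``x0`` the centre and ``dx`` the width, both in pH units.
    """

    A1: float
    A2: float
    x0: float
    dx: float

    def __post_init__(self) -> None:
        if self.A1 == self.A2:
            raise UnidentifiableFitError("A1 must differ from A2")
        if self.dx == 0:
            raise UnidentifiableFitError("dx must be nonzero")

    def to_dict(self) -> dict:
        return {"A1": self.A1, "A2": self.A2, "x0": self.x0, "dx": self.dx}

    @classmethod
    def from_dict(cls, d: dict) -> "BoltzmannParams":
        return cls(A1=d["A1"], A2=d["A2"], x0=d["x0"], dx=d["dx"])


@dataclass(frozen=True)
class ElectrodeCalibration:
    """Affine map from electrode potential (mV) to pH."""

    slope: float  # pH per mV
    intercept: float  # pH at 0 mV

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or self.slope == 0:
            raise UnidentifiableFitError("electrode slope must be finite and nonzero")


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration observation: known pH and measured steady-state value."""

    pH: float
    value: float

    def __post_init__(self) -> None:
        if not 5.0 <= self.pH <= 9.0:
            raise ValueError(f"calibration pH {self.pH} outside [5, 9]")


@dataclass(frozen=True)
class SteadyStateFit:
    """Asymptote of a mono-exponential plateau fit, with provenance."""

    value: float
    tau_s: float | None
    y0: float | None
    converged: bool
    method: str  # "exponential" or "final-quartile-mean"


@dataclass(frozen=True)
class BoltzmannFit:
    """A fitted calibration sigmoid plus a minimal fit report."""

    params: BoltzmannParams
    residual_norm: float
    converged: bool
    n_points: int


# ---------------------------------------------------------------------------
# steady-state extraction
# ---------------------------------------------------------------------------

def _expo(t, y_ss, y0, tau):
    return y_ss + (y0 - y_ss) * np.exp(-t / tau)


def steady_state_fit(segment: Trace) -> SteadyStateFit:
    """Fit ``y(t) = y_ss + (y0 - y_ss) exp(-t/tau)`` and return the asymptote.

    The fit is performed on time measured from the first sample, so the
    result is invariant under time-shifting the segment.  When the nonlinear
    fit fails to converge the mean of the final quartile of samples is used
    instead and the fallback is recorded in ``method``.
    """
    if len(segment) < 4:
        raise InsufficientDataError(
            f"steady-state fit needs >= 4 points, got {len(segment)}"
        )
    t = segment.t - segment.t[0]
    y = segment.y
    n4 = max(1, len(y) // 4)
    tail_mean = float(np.mean(y[-n4:]))
    if np.ptp(y) == 0.0:
        return SteadyStateFit(float(y[0]), None, None, True, "exponential")
    span = max(float(t[-1]), 1e-9)
    p0 = (tail_mean, float(y[0]), span / 5.0)
    try:
        popt, _ = optimize.curve_fit(
            _expo,
            t,
            y,
            p0=p0,
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, 1e3 * span]),
            maxfev=5000,
        )
    except (RuntimeError, optimize.OptimizeWarning, ValueError):
        return SteadyStateFit(tail_mean, None, None, False, "final-quartile-mean")
    y_ss, y0, tau = (float(v) for v in popt)
    # a time constant far beyond the segment span, or an asymptote outside
    # the observed range, means the plateau was never observed and the
    # extrapolated asymptote is unidentified -> use the fallback estimate
    margin = 0.5 * float(np.ptp(y))
    runaway = (
        not np.isfinite(y_ss)
        or tau > 3.0 * span
        or y_ss < y.min() - margin
        or y_ss > y.max() + margin
    )
    if runaway:
        return SteadyStateFit(tail_mean, None, None, False, "final-quartile-mean")
    return SteadyStateFit(y_ss, tau, y0, True, "exponential")


def steady_state_value(segment: Trace) -> float:
    """The plateau a segment is relaxing toward (see :func:`steady_state_fit`)."""
    return steady_state_fit(segment).value


# ---------------------------------------------------------------------------
# Boltzmann calibration
# ---------------------------------------------------------------------------

def boltzmann_ratio(pH, params: BoltzmannParams):
    """Forward evaluation of the calibration sigmoid at ``pH`` (vectorised)."""
    pH = np.asarray(pH, dtype=float)
    out = (params.A1 - params.A2) / (
        1.0 + np.exp((pH - params.x0) / params.dx)
    ) + params.A2
    return out if out.ndim else float(out)


def _sigmoid_basis(x, x0, dx):
    return 1.0 / (1.0 + np.exp((x - x0) / dx))


def _grid_init(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Coarse variable-projection search: the model is linear in (A1-A2, A2)
    once (x0, dx) are fixed, so scan a grid and solve the linear subproblem."""
    span = float(np.ptp(x))
    best = None
    for x0 in np.linspace(x.min(), x.max(), 25):
        for dx in np.concatenate([np.geomspace(0.02 * span, 2 * span, 15),
                                  -np.geomspace(0.02 * span, 2 * span, 15)]):
            s = _sigmoid_basis(x, x0, dx)
            design = np.column_stack([s, np.ones_like(s)])
            coef, res, *_ = np.linalg.lstsq(design, y, rcond=None)
            sse = float(res[0]) if res.size else float(
                np.sum((design @ coef - y) ** 2)
            )
            if best is None or sse < best[0]:
                best = (sse, coef[0] + coef[1], coef[1], x0, dx)
    _, a1, a2, x0, dx = best
    return a1, a2, x0, dx


def fit_boltzmann(points: Sequence[CalibrationPoint]) -> BoltzmannFit:
    """Least-squares fit of the calibration sigmoid to staircase plateaus.

    Requires at least four distinct pH values spanning at least one pH unit.
    Constant measured values leave (A1, A2, x0, dx) unidentifiable.
    """
    x = np.array([p.pH for p in points], dtype=float)
    y = np.array([p.value for p in points], dtype=float)
    distinct = np.unique(x)
    if distinct.size < 4:
        raise InsufficientDataError(
            f"Boltzmann fit needs >= 4 distinct pH values, got {distinct.size}"
        )
    if np.ptp(distinct) < 1.0:
        raise InsufficientDataError(
            f"calibration points span {np.ptp(distinct):.2f} pH units; "
            "need >= 1"
        )
    scale = max(abs(float(np.mean(y))), 1.0)
    if np.ptp(y) <= 1e-9 * scale:
        raise UnidentifiableFitError(
            "measured values are constant across pH; A1 ~= A2"
        )

    def model(x, a1, a2, x0, dx):
        return (a1 - a2) / (1.0 + np.exp((x - x0) / dx)) + a2

    p0 = _grid_init(x, y)
    converged = True
    try:
        popt, _ = optimize.curve_fit(model, x, y, p0=p0, maxfev=10000)
    except (RuntimeError, ValueError):
        popt, converged = p0, False
    resid = float(np.linalg.norm(model(x, *popt) - y))
    params = BoltzmannParams(*(float(v) for v in popt))
    return BoltzmannFit(params, resid, converged, len(points))


def ratio_to_ph(R, params: BoltzmannParams, eps: float = 1e-9):
    """Invert the calibration sigmoid: exact algebraic inverse of
    :func:`boltzmann_ratio`.

    ``R`` must lie strictly inside the open interval bounded by ``A1`` and
    ``A2``.  Ratios inside the domain but grazing a plateau closer than
    ``eps`` are clamped inward (noise can touch the asymptotes); ratios on
    or beyond a plateau raise :class:`CalibrationDomainError` naming the
    offending sample.
    """
    R_arr = np.atleast_1d(np.asarray(R, dtype=float))
    lo, hi = sorted((params.A1, params.A2))
    inside = (R_arr > lo) & (R_arr < hi)
    if not np.all(inside):
        bad = int(np.flatnonzero(~inside)[0])
        raise CalibrationDomainError(
            f"ratio {R_arr[bad]!r} (sample {bad}) outside the invertible "
            f"open interval ({lo}, {hi})"
        )
    clamped = np.clip(R_arr, lo + eps, hi - eps)
    pH = params.x0 + params.dx * np.log(
        (params.A1 - params.A2) / (clamped - params.A2) - 1.0
    )
    return pH if np.ndim(R) else float(pH[0])


def ratio_trace_to_ph(trace: Trace, params: BoltzmannParams,
                      eps: float = 1e-9) -> Trace:
    """Convert a ratio trace to a pH trace via the fitted sigmoid.

    Samples clamped at the domain boundary are flagged in the output
    metadata under ``clamped_samples``.
    """
    if trace.kind != "ratio":
        raise TraceKindError(f"expected a ratio trace, got {trace.kind!r}")
    lo, hi = sorted((params.A1, params.A2))
    grazing = ((trace.y <= lo + eps) | (trace.y >= hi - eps))
    pH = ratio_to_ph(trace.y, params, eps=eps)
    return trace.with_values(
        pH,
        "pH",
        calibration=params.to_dict(),
        clamped_samples=[int(i) for i in np.flatnonzero(grazing)],
    )


# ---------------------------------------------------------------------------
# electrode calibration
# ---------------------------------------------------------------------------

def calibrate_electrode(points: Sequence[CalibrationPoint]) -> ElectrodeCalibration:
    """Ordinary least-squares line ``pH = intercept + slope * V_e``.

    With exactly two points this is the exact interpolant through them.
    """
    if len(points) < 2:
        raise InsufficientDataError("electrode calibration needs >= 2 points")
    V = np.array([p.value for p in points], dtype=float)
    pH = np.array([p.pH for p in points], dtype=float)
    if np.ptp(V) == 0:
        raise UnidentifiableFitError(
            "identical calibration potentials; line is singular"
        )
    slope, intercept = np.polyfit(V, pH, 1)
    return ElectrodeCalibration(slope=float(slope), intercept=float(intercept))


def voltage_to_ph(trace: Trace, cal: ElectrodeCalibration) -> Trace:
    """Element-wise affine map of an electrode-potential trace to pH."""
    if trace.kind != "potential_mV":
        raise TraceKindError(
            f"expected a potential_mV trace, got {trace.kind!r}"
        )
    pH = cal.intercept + cal.slope * trace.y
    return trace.with_values(
        pH, "pH", calibration={"slope": cal.slope, "intercept": cal.intercept}
    )
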