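"""Seeded generators for every input the pipeline consumes.

No raw recordings accompany the study design this package implements, so
each analysis stage is exercised on synthetic data whose generating
parameters are known exactly.  Every generator is a pure function of its
parameters and a seed (bit-identical regeneration) and returns the dataset
together with an :class:`ExperimentGroundTruth` carrying the true values
the estimators are later asked to recover.

The physiology stand-ins are deliberately minimal but dimensionally
faithful:

* nigericin calibration staircases relax mono-exponentially to the
  Boltzmann ratio of each pH step, with additive Gaussian ratio noise;
* lactate pulses acidify with an initial slope set by Michaelis–Menten
  influx ``J = J_max·c/(c+K_m)`` divided by the buffer capacity, relaxing
  mono-exponentially toward a shifted quasi-steady pH; withdrawal mirrors
  the response back to baseline; a terminal CO2/HCO3- pulse acidifies to
  the steady state a closed buffer of strength β_true would show;
* electrode recordings map the same pH kinetics through the inverse
  electrode line, plus optional linear drift, with two calibration baths
  (pH 7.0 and 6.4) prepended;
* the 18O assay is a first-order depletion cascade across m/z 49 → 47 → 45
  with the per-atom exchange rate stepping from θ to θ·(1+U) at lysate
  addition, and optional Poisson counting noise;
* nuclei images are jittered disks with a controllable fraction of
  touching pairs and recorded centres/radii.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .calibration import BoltzmannParams, ElectrodeCalibration, boltzmann_ratio
from .errors import PlacementError, TraceValidationError
from .flux_quant import hco3_intracellular
from .isotope_ca import IsotopeSeries
from .image_quant import NucleiImage
from .trace_model import ApplicationProtocol, SolutionSpec, Trace


@dataclass(frozen=True)
class ExperimentGroundTruth:
    """True generating parameters of a synthetic dataset."""

    kind: str
    seed: int
    params: dict

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {"kind": self.kind, "seed": self.seed, "params": self.params},
                indent=2,
                default=_jsonify,
            ),
            encoding="utf-8",
        )


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


# ---------------------------------------------------------------------------
# calibration staircase
# ---------------------------------------------------------------------------

def gen_calibration_trace(
    params: BoltzmannParams,
    ph_steps=(6.0, 6.5, 7.0, 7.5, 8.0),
    step_duration_s: float = 150.0,
    tau_s: float = 10.0,
    noise_sd: float = 0.01,
    dt_s: float = 2.5,
    seed: int = 0,
) -> tuple[Trace, ExperimentGroundTruth]:
    """Nigericin calibration staircase of the emission ratio.

    Within each step the ratio relaxes mono-exponentially (time constant
    ``tau_s``) toward the Boltzmann ratio of that step's pH, with i.i.d.
    Gaussian noise on top.  Step boundaries are recorded in the ground
    truth so analyses can segment the plateaus.
    """
    if len(ph_steps) < 2:
        raise TraceValidationError("need at least 2 calibration steps")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, step_duration_s * len(ph_steps), dt_s)
    y = np.empty_like(t)
    current = float(boltzmann_ratio(ph_steps[0], params))
    windows = []
    for k, ph in enumerate(ph_steps):
        target = float(boltzmann_ratio(ph, params))
        t0, t1 = k * step_duration_s, (k + 1) * step_duration_s
        sel = (t >= t0) & (t < t1)
        y[sel] = target + (current - target) * np.exp(-(t[sel] - t0) / tau_s)
        current = target + (current - target) * np.exp(
            -(t1 - t0) / tau_s
        )
        windows.append((t0, t1))
    y = y + rng.normal(0.0, noise_sd, size=y.shape)
    gt = ExperimentGroundTruth(
        "calibration_staircase",
        seed,
        {
            "boltzmann": params.to_dict(),
            "ph_steps": list(ph_steps),
            "step_windows_s": windows,
            "step_duration_s": step_duration_s,
            "tau_s": tau_s,
            "noise_sd": noise_sd,
            "dt_s": dt_s,
        },
    )
    return Trace(t, y, "ratio", {"synthetic": True}), gt


# ---------------------------------------------------------------------------
# lactate / CO2 pH kinetics
# ---------------------------------------------------------------------------

_CO2_SOLUTES = {"co2", "co2/hco3", "co2/hco3-"}


def _co2_steady_ph(pH_pre: float, beta_true: float,
                   solution: SolutionSpec) -> float:
    """pH at which the CO2-pulse acidification of a closed buffer of
    strength ``beta_true`` balances the bicarbonate formed:
    hco3_i(pH) = beta_true * (pH_pre - pH)."""
    from scipy.optimize import brentq

    f = lambda p: hco3_intracellular(p, solution) - beta_true * (pH_pre - p)
    lo = pH_pre - 3.0
    if f(lo) > 0:  # extremely strong buffer: shift barely resolvable
        lo = pH_pre - 1e-6
    return float(brentq(f, lo, pH_pre - 1e-12, xtol=1e-12))


def _lactate_ph_trajectory(
    t: np.ndarray,
    protocol: ApplicationProtocol,
    J_max: float,
    K_m: float,
    beta_true: float,
    tau_s: float,
    baseline_pH: float,
    solution: SolutionSpec,
) -> tuple[np.ndarray, dict]:
    """Noiseless piecewise mono-exponential pH trajectory, plus ground truth."""
    events = sorted(
        enumerate(protocol.events), key=lambda kv: kv[1].t_start
    )
    # breakpoints: (time, target, tau); between events relax to baseline
    segs: list[tuple[float, float]] = [(float(t[0]), baseline_pH)]
    truth_J: dict[int, float] = {}
    truth_co2: dict[int, float] = {}

    def ph_at(time: float) -> float:
        # evaluate trajectory value at `time` by walking segments in order
        s = sorted(segs)
        val = baseline_pH
        for k, (t0, target) in enumerate(s):
            t1 = s[k + 1][0] if k + 1 < len(s) else np.inf
            upper = min(t1, time)
            if upper <= t0:
                break
            val = target + (val - target) * np.exp(-(upper - t0) / tau_s)
            if upper >= time:
                break
        return val

    for idx, ev in events:
        ph_start = ph_at(ev.t_start)
        if ev.solute.lower() in _CO2_SOLUTES:
            target = _co2_steady_ph(ph_start, beta_true, solution)
            truth_co2[idx] = target
        else:
            J = J_max * ev.concentration / (ev.concentration + K_m)
            truth_J[idx] = J
            rate_per_s = (J / beta_true) / 60.0  # pH units per second
            target = ph_start - rate_per_s * tau_s
        segs.append((float(ev.t_start), float(target)))
        segs.append((float(ev.t_end), baseline_pH))
    segs.sort(key=lambda s: s[0])

    y = np.empty_like(t)
    val = baseline_pH
    for k, (t0, target) in enumerate(segs):
        t1 = segs[k + 1][0] if k + 1 < len(segs) else np.inf
        sel = (t >= t0) & (t < t1)
        y[sel] = target + (val - target) * np.exp(-(t[sel] - t0) / tau_s)
        if np.isfinite(t1):
            val = target + (val - target) * np.exp(-(t1 - t0) / tau_s)
    truth = {"J_true_mM_per_min": truth_J, "co2_steady_pH": truth_co2}
    return y, truth


def gen_lactate_experiment(
    protocol: ApplicationProtocol,
    J_max: float = 4.0,
    K_m: float = 5.0,
    beta_true: float = 20.0,
    tau_s: float = 60.0,
    baseline_pH: float = 7.2,
    noise_sd: float = 0.005,
    dt_s: float = 2.5,
    tail_s: float = 120.0,
    solution: SolutionSpec | None = None,
    seed: int = 0,
) -> tuple[Trace, ExperimentGroundTruth]:
    """Intracellular pH response to lactate (and CO2) pulses.

    During application of concentration ``c`` the initial acidification
    rate is ``-(J_max·c/(c+K_m))/beta_true`` (Michaelis–Menten influx over
    buffering), relaxing with time constant ``tau_s``; withdrawal mirrors
    back toward baseline.  Protocol events whose solute is ``CO2`` produce
    an acidification whose steady state satisfies the buffering relation
    with ``beta_true``, so the buffer-capacity estimator can be validated
    against it.  Defaults follow the study conditions: K_m ≈ 5 mM lactate,
    0.4 Hz imaging, baseline pH 7.2.
    """
    solution = solution or SolutionSpec()
    rng = np.random.default_rng(seed)
    t_end = max(ev.t_end for ev in protocol.events) + tail_s
    t = np.arange(0.0, t_end, dt_s)
    y, truth = _lactate_ph_trajectory(
        t, protocol, J_max, K_m, beta_true, tau_s, baseline_pH, solution
    )
    y_noisy = y + rng.normal(0.0, noise_sd, size=y.shape)
    gt = ExperimentGroundTruth(
        "lactate_experiment",
        seed,
        {
            "J_max_mM_per_min": J_max,
            "K_m_mM": K_m,
            "beta_true_mM_per_pH": beta_true,
            "tau_s": tau_s,
            "baseline_pH": baseline_pH,
            "noise_sd": noise_sd,
            "dt_s": dt_s,
            "solution": vars(solution),
            **truth,
        },
    )
    return Trace(t, y_noisy, "pH", {"synthetic": True}), gt


def gen_electrode_recording(
    protocol: ApplicationProtocol,
    J_max: float = 4.0,
    K_m: float = 5.0,
    beta_true: float = 20.0,
    tau_s: float = 60.0,
    baseline_pH: float = 7.2,
    electrode: ElectrodeCalibration | None = None,
    drift_mV_per_min: float = 0.0,
    noise_sd_mV: float = 0.0,
    cal_segment_s: float = 60.0,
    cal_phs: tuple[float, float] = (7.0, 6.4),
    dt_s: float = 0.5,
    tail_s: float = 120.0,
    solution: SolutionSpec | None = None,
    seed: int = 0,
) -> tuple[Trace, ExperimentGroundTruth]:
    """Microelectrode potential recording with calibration baths prepended.

    The pH trajectory of :func:`gen_lactate_experiment` is mapped through
    the inverse electrode line ``V = (pH - intercept)/slope``; two
    calibration segments (pH 7.0 then 6.4) precede the intracellular
    recording at negative times, so protocol event times stay aligned
    with the trace clock.  Linear drift plus Gaussian noise are added to
    the potential.  Ground truth carries the underlying pH trajectory.
    """
    electrode = electrode or ElectrodeCalibration(slope=-1.0 / 58.0,
                                                  intercept=7.0)
    solution = solution or SolutionSpec()
    rng = np.random.default_rng(seed)
    rec_offset = 2 * cal_segment_s
    t_end = max(ev.t_end for ev in protocol.events) + tail_s
    t_rec = np.arange(0.0, t_end, dt_s)
    pH_rec, truth = _lactate_ph_trajectory(
        t_rec, protocol, J_max, K_m, beta_true, tau_s, baseline_pH, solution
    )
    t_cal = np.arange(-rec_offset, 0.0, dt_s)
    pH_cal = np.where(t_cal < -cal_segment_s, cal_phs[0], cal_phs[1])
    t = np.concatenate([t_cal, t_rec])
    pH = np.concatenate([pH_cal, pH_rec])
    V = (pH - electrode.intercept) / electrode.slope
    V = V + drift_mV_per_min * t / 60.0
    V = V + rng.normal(0.0, noise_sd_mV, size=V.shape)
    gt = ExperimentGroundTruth(
        "electrode_recording",
        seed,
        {
            "electrode": {"slope": electrode.slope,
                          "intercept": electrode.intercept},
            "drift_mV_per_min": drift_mV_per_min,
            "noise_sd_mV": noise_sd_mV,
            "cal_windows_s": [(-rec_offset, -cal_segment_s),
                              (-cal_segment_s, 0.0)],
            "cal_phs": list(cal_phs),
            "recording_start_s": 0.0,
            "true_pH": pH,
            "J_max_mM_per_min": J_max,
            "K_m_mM": K_m,
            "beta_true_mM_per_pH": beta_true,
            "tau_s": tau_s,
            "baseline_pH": baseline_pH,
            **truth,
        },
    )
    return Trace(t, V, "potential_mV", {"synthetic": True}), gt


# ---------------------------------------------------------------------------
# 18O depletion cascade
# ---------------------------------------------------------------------------

def _cascade_closed_form(
    dt: np.ndarray, a0: float, b0: float, c0: float, theta: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact solution of d49/dt = -2θ·49, d47/dt = 2θ·49 - θ·47,
    d45/dt = θ·47 (total conserved)."""
    a = a0 * np.exp(-2.0 * theta * dt)
    b = (b0 + 2.0 * a0) * np.exp(-theta * dt) - 2.0 * a0 * np.exp(
        -2.0 * theta * dt
    )
    c = (a0 + b0 + c0) - a - b
    return a, b, c


def gen_isotope_series(
    theta_uncat: float = 1e-3,
    U_true: float = 5.0,
    addition_time_s: float = 300.0,
    duration_s: float = 600.0,
    counts_scale: float = 1e4,
    dt_s: float = 2.0,
    poisson_noise: bool = True,
    seed: int = 0,
) -> tuple[IsotopeSeries, ExperimentGroundTruth]:
    """First-order 18O depletion cascade with a lysate-addition step.

    The per-18O-atom exchange rate is ``theta_uncat`` (1/s) before
    ``addition_time_s`` and ``theta_uncat*(1+U_true)`` after, so the log
    enrichment decays with slope ``-2θ/ln 10`` in each phase and the
    catalyzed/uncatalyzed slope ratio encodes ``U_true`` Badger units.
    The record starts as pure doubly labelled CO2 (all abundance at
    m/z 49).  Poisson counting noise at ``counts_scale`` mean counts is
    optional.
    """
    if U_true < 0:
        raise TraceValidationError("U_true must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, dt_s)
    pre = t < addition_time_s
    a = np.empty_like(t)
    b = np.empty_like(t)
    c = np.empty_like(t)
    a[pre], b[pre], c[pre] = _cascade_closed_form(
        t[pre], counts_scale, 0.0, 0.0, theta_uncat
    )
    a_add, b_add, c_add = _cascade_closed_form(
        np.array([addition_time_s]), counts_scale, 0.0, 0.0, theta_uncat
    )
    theta_cat = theta_uncat * (1.0 + U_true)
    a[~pre], b[~pre], c[~pre] = _cascade_closed_form(
        t[~pre] - addition_time_s,
        float(a_add[0]),
        float(b_add[0]),
        float(c_add[0]),
        theta_cat,
    )
    if poisson_noise:
        a = rng.poisson(a).astype(float)
        b = rng.poisson(b).astype(float)
        c = rng.poisson(c).astype(float)
        # keep the container invariant (total > 0) even in extreme tails
        dead = (a + b + c) == 0
        c[dead] = 1.0
    series = IsotopeSeries(t, c, b, a, {"synthetic": True})
    gt = ExperimentGroundTruth(
        "isotope_series",
        seed,
        {
            "theta_uncat_per_s": theta_uncat,
            "theta_cat_per_s": theta_cat,
            "U_true": U_true,
            "addition_time_s": addition_time_s,
            "duration_s": duration_s,
            "counts_scale": counts_scale,
            "poisson_noise": poisson_noise,
            "le_slope_uncat_per_min": -2.0 * theta_uncat / np.log(10.0) * 60.0,
            "le_slope_cat_per_min": -2.0 * theta_cat / np.log(10.0) * 60.0,
        },
    )
    return series, gt


# ---------------------------------------------------------------------------
# nuclei images
# ---------------------------------------------------------------------------

def gen_nuclei_image(
    n_nuclei: int = 100,
    radius_px_mean: float = 8.0,
    radius_px_sd: float = 1.0,
    overlap_fraction: float = 0.0,
    intensity: int = 200,
    image_shape: tuple[int, int] = (512, 512),
    pixel_size_um: float = 1.0,
    texture_sd: float = 10.0,
    seed: int = 0,
    max_tries: int = 5000,
) -> tuple[NucleiImage, ExperimentGroundTruth]:
    """Disk nuclei with a controllable fraction of touching pairs.

    ``overlap_fraction`` is the fraction of nuclei placed as fused pairs
    (centre separation 0.75·(r1+r2), i.e. overlapping but with two distinct
    distance-transform peaks); the remainder are mutually disjoint.  All
    centres, radii and pair memberships are recorded.  Raises
    :class:`PlacementError` when the requested density cannot be placed.
    """
    if n_nuclei < 0:
        raise TraceValidationError("n_nuclei must be >= 0")
    if not 0.0 <= overlap_fraction < 1.0:
        raise TraceValidationError("overlap_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    h, w = image_shape
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    pairs: list[tuple[int, int]] = []

    def draw_radius() -> float:
        return float(
            np.clip(rng.normal(radius_px_mean, radius_px_sd),
                    2.0, 0.25 * min(h, w))
        )

    def fits(cy, cx, r, skip: set[int]) -> bool:
        if not (r + 1 <= cy <= h - r - 2 and r + 1 <= cx <= w - r - 2):
            return False
        for i, ((oy, ox), orad) in enumerate(zip(centers, radii)):
            if i in skip:
                continue
            if np.hypot(cy - oy, cx - ox) < r + orad + 3.0:
                return False
        return True

    n_paired = 2 * int(round(overlap_fraction * n_nuclei / 2.0))
    n_pairs = n_paired // 2
    n_single = n_nuclei - n_paired

    for _ in range(n_pairs):
        for attempt in range(max_tries):
            r1, r2 = draw_radius(), draw_radius()
            cy = rng.uniform(0, h)
            cx = rng.uniform(0, w)
            ang = rng.uniform(0, 2 * np.pi)
            d = 0.75 * (r1 + r2)
            cy2, cx2 = cy + d * np.sin(ang), cx + d * np.cos(ang)
            # the partner may touch only its anchor
            if fits(cy, cx, r1 + d, set()) and fits(cy2, cx2, r2, {len(centers)}):
                i1 = len(centers)
                centers.append((cy, cx))
                radii.append(r1)
                centers.append((cy2, cx2))
                radii.append(r2)
                pairs.append((i1, i1 + 1))
                break
        else:
            raise PlacementError(
                f"could not place fused pair {len(pairs) + 1} of {n_pairs}"
            )

    for k in range(n_single):
        for attempt in range(max_tries):
            r = draw_radius()
            cy = rng.uniform(0, h)
            cx = rng.uniform(0, w)
            if fits(cy, cx, r, set()):
                centers.append((cy, cx))
                radii.append(r)
                break
        else:
            raise PlacementError(
                f"could not place nucleus {n_paired + k + 1} of {n_nuclei}"
            )

    img = np.zeros((h, w), dtype=float)
    for (cy, cx), r in zip(centers, radii):
        y0, y1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
        x0, x1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1][(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = intensity
    if texture_sd > 0:
        fg = img > 0
        img[fg] += rng.normal(0.0, texture_sd, size=int(fg.sum()))
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    gt = ExperimentGroundTruth(
        "nuclei_image",
        seed,
        {
            "n_nuclei": n_nuclei,
            "centers_yx": [list(c) for c in centers],
            "radii_px": radii,
            "touching_pairs": [list(p) for p in pairs],
            "overlap_fraction": overlap_fraction,
            "intensity": intensity,
            "image_shape": list(image_shape),
            "pixel_size_um": pixel_size_um,
            "texture_sd": texture_sd,
            "radius_px_mean": radius_px_mean,
            "radius_px_sd": radius_px_sd,
        },
    )
    return NucleiImage(img, pixel_size_um), gt
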