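"""18O isotope-exchange carbonic-anhydrase activity assay.

Carbonic-anhydrase activity is measured mass-spectrometrically by following
the loss of 18O from doubly labelled 13C18O2 through repeated hydration and
dehydration of CO2/HCO3-.  The ion currents at m/z 49 (13C18O18O), 47
(13C18O16O) and 45 (13C16O16O) are reduced to the *log enrichment*

.. math:: LE = \\log_{10}\\left(\\frac{100 \\cdot a_{49}}{a_{49}+a_{47}+a_{45}}\\right)

which decays linearly in time for first-order 18O exchange.  The assay
compares the depletion slope of the bare reaction with the slope after
adding cell lysate; one enzyme unit (Badger convention) corresponds to 100%
stimulation of the non-catalyzed depletion, i.e.
``units = catalyzed_rate / uncatalyzed_rate - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    InconsistentAssayError,
    InsufficientDataError,
    TraceValidationError,
    ZeroRateError,
)
from .flux_quant import _ols_slope
from .trace_model import Trace, _parse_columns

#: Default lysate volume: a batch of 20 oocytes lysed in 80 µl saline.
DEFAULT_SAMPLE_VOLUME_ML = 0.08


@dataclass(frozen=True)
class IsotopeSeries:
    """Ion-current abundances at m/z 45, 47 and 49 versus time."""

    t: np.ndarray
    a45: np.ndarray
    a47: np.ndarray
    a49: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("t", "a45", "a47", "a49"):
            arr = np.asarray(getattr(self, name), dtype=float)
            arr.flags.writeable = False
            arrays[name] = arr
            object.__setattr__(self, name, arr)
        n = len(arrays["t"])
        if any(len(a) != n for a in arrays.values()):
            raise TraceValidationError("abundance channels differ in length")
        if n == 0:
            raise TraceValidationError("empty isotope series")
        if n > 1 and not np.all(np.diff(arrays["t"]) > 0):
            raise TraceValidationError("time must be strictly increasing")
        for name in ("a45", "a47", "a49"):
            if np.any(arrays[name] < 0) or not np.all(np.isfinite(arrays[name])):
                raise TraceValidationError(f"{name} must be finite and >= 0")
        total = arrays["a45"] + arrays["a47"] + arrays["a49"]
        if np.any(total <= 0):
            i = int(np.flatnonzero(total <= 0)[0])
            raise TraceValidationError(
                f"total abundance is zero at sample {i} (t={arrays['t'][i]})"
            )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def total(self) -> np.ndarray:
        return self.a45 + self.a47 + self.a49


def read_isotope_series(path) -> IsotopeSeries:
    """Read a 4-column delimited text file (t, a45, a47, a49)."""
    data = _parse_columns(path, 4)
    return IsotopeSeries(
        data[:, 0], data[:, 1], data[:, 2], data[:, 3], {"source": str(path)}
    )


def write_isotope_series(path, series: IsotopeSeries,
                         delimiter: str = ",") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"time_s{delimiter}a45{delimiter}a47{delimiter}a49\n")
        for row in zip(series.t, series.a45, series.a47, series.a49):
            fh.write(delimiter.join(repr(float(v)) for v in row) + "\n")


@dataclass(frozen=True)
class CAActivityResult:
    """Enzyme activity from paired uncatalyzed/catalyzed depletion slopes.

    ``units`` is the raw Badger statistic ``|cat|/|uncat| - 1`` and may be
    negative for a (nonsensical) decelerated assay; such results are
    flagged via ``negative`` rather than silently clipped.
    """

    uncat_rate: float  # LE-units/min
    cat_rate: float  # LE-units/min
    units: float  # U, dimensionless
    units_per_ml: float  # U/ml
    sample_volume_ml: float

    @property
    def negative(self) -> bool:
        return self.units < 0

    @property
    def stimulation_percent(self) -> float:
        """Stimulation of the non-catalyzed depletion, in percent (1 U = 100%)."""
        return self.units * 100.0


def log_enrichment(series: IsotopeSeries) -> Trace:
    """Reduce an isotope series to its log-enrichment trace.

    ``LE = log10(a49 * 100 / (a49 + a47 + a45))`` per sample.  Samples with
    zero m/z-49 abundance carry no enrichment information; they are dropped
    and their indices recorded in the output metadata.
    """
    keep = series.a49 > 0
    dropped = [int(i) for i in np.flatnonzero(~keep)]
    if not np.any(keep):
        raise TraceValidationError("no samples with a49 > 0")
    le = np.log10(100.0 * series.a49[keep] / series.total[keep])
    meta = dict(series.meta)
    meta["dropped_samples"] = dropped
    return Trace(series.t[keep], le, "log_enrichment", meta)


def enrichment_rate(le: Trace, window: tuple[float, float]) -> float:
    """OLS slope of the log enrichment over ``window``, per minute."""
    t_a, t_b = window
    sel = (le.t >= t_a) & (le.t <= t_b)
    if int(sel.sum()) < 3:
        raise InsufficientDataError(
            f"window [{t_a}, {t_b}] s holds {int(sel.sum())} samples; need >= 3"
        )
    slope, _ = _ols_slope(le.t[sel], le.y[sel])
    return slope * 60.0


def ca_units(
    cat_rate: float,
    uncat_rate: float,
    sample_volume_ml: float = DEFAULT_SAMPLE_VOLUME_ML,
) -> CAActivityResult:
    """Enzyme units from catalyzed and uncatalyzed depletion slopes.

    Both slopes must be negative (18O is depleted).  One unit corresponds to
    100% stimulation of the non-catalyzed depletion, so
    ``units = |cat_rate| / |uncat_rate| - 1``; ``units_per_ml`` normalises
    by the lysate sample volume.
    """
    if uncat_rate == 0:
        raise ZeroRateError("uncatalyzed depletion rate is zero")
    if cat_rate != 0 and np.sign(cat_rate) != np.sign(uncat_rate):
        raise InconsistentAssayError(
            f"catalyzed ({cat_rate}) and uncatalyzed ({uncat_rate}) rates "
            "have opposite signs"
        )
    units = abs(cat_rate) / abs(uncat_rate) - 1.0
    return CAActivityResult(
        uncat_rate=uncat_rate,
        cat_rate=cat_rate,
        units=units,
        units_per_ml=units / sample_volume_ml,
        sample_volume_ml=sample_volume_ml,
    )


def assay_from_series(
    series: IsotopeSeries,
    addition_time_s: float,
    sample_volume_ml: float = DEFAULT_SAMPLE_VOLUME_ML,
    settle_s: float = 0.0,
) -> CAActivityResult:
    """Full assay on one recording: uncatalyzed slope before lysate addition,
    catalyzed slope after, then Badger units.

    ``settle_s`` skips an initial mixing transient after the addition.
    """
    le = log_enrichment(series)
    uncat = enrichment_rate(le, (le.t[0], addition_time_s))
    cat = enrichment_rate(le, (addition_time_s + settle_s, le.t[-1]))
    return ca_units(cat, uncat, sample_volume_ml=sample_volume_ml)
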