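"""Core time-series containers and file I/O shared by every analysis stage.

The pipeline's universal currency is the :class:`Trace` — a time-stamped
scalar signal with a units tag: the raw fluorescence ratio of a ratiometric
pH dye, the potential of an ion-sensitive microelectrode, a calibrated pH,
an intracellular proton concentration, or the log enrichment of an isotope
assay.  Solution-change protocols (:class:`ApplicationProtocol`) define the
analysis windows around substrate application and withdrawal.

Time is stored in seconds throughout; rate-reporting operations convert to
per-minute at the reporting boundary.  Sampling may be irregular — nothing
downstream assumes a uniform interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import (
    TraceParseError,
    TraceValidationError,
    WindowError,
)

#: Recognised units tags for a :class:`Trace`.
TRACE_KINDS = frozenset(
    {"ratio", "potential_mV", "pH", "proton_nM", "log_enrichment"}
)


def _freeze(arr: np.ndarray) -> np.ndarray:
    out = np.asarray(arr, dtype=float)
    out.flags.writeable = False
    return out


@dataclass(frozen=True)
class Trace:
    """A scalar time series with a fixed units tag.

    Parameters
    ----------
    t : array-like
        Sample times in seconds, strictly increasing.
    y : array-like
        Measured values, one per time point, all finite.
    kind : str
        One of :data:`TRACE_KINDS`.
    meta : dict
        Free-form provenance (ROI id, cell id, applied event, ...).
    """

    t: np.ndarray
    y: np.ndarray
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = _freeze(self.t)
        y = _freeze(self.y)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)
        if self.kind not in TRACE_KINDS:
            raise TraceValidationError(
                f"unknown trace kind {self.kind!r}; expected one of "
                f"{sorted(TRACE_KINDS)}"
            )
        if t.ndim != 1 or y.ndim != 1:
            raise TraceValidationError("t and y must be one-dimensional")
        if len(t) != len(y):
            raise TraceValidationError(
                f"length mismatch: {len(t)} times vs {len(y)} values"
            )
        if len(t) == 0:
            raise TraceValidationError("empty trace")
        if not np.all(np.isfinite(t)):
            raise TraceValidationError("non-finite time stamp")
        if not np.all(np.isfinite(y)):
            raise TraceValidationError("non-finite sample value")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            i = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise TraceValidationError(
                f"time must be strictly increasing (violated at sample {i}, "
                f"t={t[i]!r})"
            )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Span of the trace in seconds."""
        return float(self.t[-1] - self.t[0])

    def with_values(self, y: np.ndarray, kind: str, **meta) -> "Trace":
        """Return a new trace on the same time base with converted values."""
        merged = dict(self.meta)
        merged.update(meta)
        return Trace(self.t, y, kind, merged)

    def crop(self, t_a: float, t_b: float, **meta) -> "Trace":
        """Sub-trace with samples in ``[t_a, t_b]``; raises if empty."""
        sel = (self.t >= t_a) & (self.t <= t_b)
        if not np.any(sel):
            raise WindowError(
                f"window [{t_a}, {t_b}] s does not intersect trace support "
                f"[{self.t[0]}, {self.t[-1]}] s"
            )
        merged = dict(self.meta)
        merged.update(meta)
        return Trace(self.t[sel], self.y[sel], self.kind, merged)


@dataclass(frozen=True)
class SolutionEvent:
    """One solution change: which solute, how much, and when."""

    solute: str
    concentration: float  # mM, or fraction for gases expressed as %CO2
    t_start: float  # s
    t_end: float  # s

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise TraceValidationError(
                f"negative concentration for {self.solute!r}"
            )
        if not self.t_start < self.t_end:
            raise TraceValidationError(
                f"event {self.solute!r}: t_start ({self.t_start}) must "
                f"precede t_end ({self.t_end})"
            )


@dataclass(frozen=True)
class ApplicationProtocol:
    """Ordered solution-change events defining the analysis windows."""

    events: tuple
    baseline: str = "control saline"

    def __post_init__(self) -> None:
        events = tuple(
            e if isinstance(e, SolutionEvent) else SolutionEvent(**e)
            for e in self.events
        )
        object.__setattr__(self, "events", events)
        # events may interleave across solutes but must not overlap within one
        by_solute: dict[str, list[SolutionEvent]] = {}
        for ev in events:
            by_solute.setdefault(ev.solute, []).append(ev)
        for solute, evs in by_solute.items():
            evs = sorted(evs, key=lambda e: e.t_start)
            for a, b in zip(evs, evs[1:]):
                if b.t_start < a.t_end:
                    raise TraceValidationError(
                        f"overlapping {solute!r} events at t={b.t_start} s"
                    )

    def __len__(self) -> int:
        return len(self.events)

    def event(self, index: int) -> SolutionEvent:
        try:
            return self.events[index]
        except IndexError:
            raise WindowError(
                f"protocol has {len(self.events)} events; "
                f"index {index} out of range"
            ) from None


@dataclass(frozen=True)
class SolutionSpec:
    """CO2/HCO3- composition of the superfusate during a buffering pulse.

    ``pK_prime`` is the apparent pK of the CO2/HCO3- system (6.1 at room
    temperature by physiological-chemistry convention); the dissolved CO2
    implied by the extracellular equilibrium is derived from it.
    """

    pco2_fraction: float = 0.05
    hco3_mM: float = 10.0
    pH_o: float = 7.0
    pK_prime: float | None = 6.1
    temperature_C: float = 22.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pco2_fraction <= 1.0:
            raise TraceValidationError("pco2_fraction must lie in [0, 1]")
        if self.hco3_mM < 0:
            raise TraceValidationError("hco3_mM must be non-negative")

    @property
    def co2_mM(self) -> float:
        """Dissolved CO2 (mM) from Henderson–Hasselbalch at equilibrium."""
        from .errors import ConfigurationError

        if self.pK_prime is None:
            raise ConfigurationError("SolutionSpec.pK_prime is not set")
        return self.hco3_mM / 10.0 ** (self.pH_o - self.pK_prime)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _sniff_delimiter(line: str) -> str:
    # comma or tab, auto-detected; decimal point only
    return "\t" if line.count("\t") >= line.count(",") and "\t" in line else ","


def _parse_columns(path, n_cols: int) -> np.ndarray:
    """Parse an n-column delimited text file; report failures by line number."""
    rows: list[list[float]] = []
    delim = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if delim is None:
                delim = _sniff_delimiter(line)
            parts = [p.strip() for p in line.split(delim)]
            if len(parts) != n_cols:
                if lineno == 1 or (not rows and _looks_like_header(parts)):
                    continue
                raise TraceParseError(
                    f"{path}:{lineno}: expected {n_cols} columns, "
                    f"got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                if not rows and _looks_like_header(parts):
                    continue  # optional header row
                raise TraceParseError(
                    f"{path}:{lineno}: malformed row {line!r}"
                ) from None
    if not rows:
        raise TraceParseError(f"{path}: no data rows found")
    return np.asarray(rows, dtype=float)


def _looks_like_header(parts: Sequence[str]) -> bool:
    for p in parts:
        try:
            float(p)
        except ValueError:
            return True
    return False


def read_trace(path, kind: str) -> Trace:
    """Read a two-column delimited text file (time s, value) as a Trace.

    Comma- or tab-delimited, optional single header line, ``#`` comments
    ignored.  Non-monotone time raises :class:`TraceValidationError`.
    """
    data = _parse_columns(path, 2)
    return Trace(data[:, 0], data[:, 1], kind, {"source": str(path)})


def write_trace(path, trace: Trace, delimiter: str = ",") -> None:
    """Write a trace as two-column delimited text (round-trips exactly)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# kind={trace.kind}\n")
        fh.write(f"time_s{delimiter}value\n")
        for t, y in zip(trace.t, trace.y):
            fh.write(f"{float(t)!r}{delimiter}{float(y)!r}\n")


def read_protocol(path) -> ApplicationProtocol:
    """Read a YAML/JSON protocol file.

    Accepts either a bare list of events or a mapping with keys ``events``
    and optional ``baseline``; each event has keys
    ``{solute, concentration, start, end}``.
    """
    text = Path(path).read_text(encoding="utf-8")
    doc = yaml.safe_load(text)  # YAML superset also parses JSON
    if isinstance(doc, dict):
        raw_events = doc.get("events", [])
        baseline = doc.get("baseline", "control saline")
    else:
        raw_events, baseline = doc, "control saline"
    events = [
        SolutionEvent(
            solute=str(e["solute"]),
            concentration=float(e["concentration"]),
            t_start=float(e["start"]),
            t_end=float(e["end"]),
        )
        for e in raw_events
    ]
    return ApplicationProtocol(tuple(events), baseline=baseline)


def write_protocol(path, protocol: ApplicationProtocol) -> None:
    doc = {
        "baseline": protocol.baseline,
        "events": [
            {
                "solute": e.solute,
                "concentration": e.concentration,
                "start": e.t_start,
                "end": e.t_end,
            }
            for e in protocol.events
        ],
    }
    Path(path).write_text(
        yaml.safe_dump(doc, sort_keys=False), encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_trace(
    trace: Trace,
    protocol: ApplicationProtocol,
    event_index: int,
    pad_s: float = 0.0,
) -> Trace:
    """Sub-trace covering one protocol event, padded and clipped to support.

    Returns the samples in ``[t_start - pad_s, t_end + pad_s]`` clipped to the
    trace support.  Samples are never reordered or altered.  The selected
    event is recorded in the sub-trace's metadata.
    """
    ev = protocol.event(event_index)
    return trace.crop(
        ev.t_start - pad_s,
        ev.t_end + pad_s,
        event={
            "index": event_index,
            "solute": ev.solute,
            "concentration": ev.concentration,
            "t_start": ev.t_start,
            "t_end": ev.t_end,
            "pad_s": pad_s,
        },
    )
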