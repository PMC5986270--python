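import numpy as np
import pytest

from protonflux import (
    ApplicationProtocol,
    BoltzmannParams,
    SolutionSpec,
    Trace,
)
from protonflux.trace_model import SolutionEvent


@pytest.fixture
def bparams() -> BoltzmannParams:
    """Calibration sigmoid used throughout: acidic plateau 1.6, alkaline 0.4,
    midpoint at the dye-typical pK ~7, width 0.5 pH units."""
    return BoltzmannParams(A1=1.6, A2=0.4, x0=7.0, dx=0.5)


@pytest.fixture
def solution() -> SolutionSpec:
    """5% CO2 / 10 mM HCO3- superfusate at pH_o 7.0, pK' 6.1."""
    return SolutionSpec()


@pytest.fixture
def lactate_protocol() -> ApplicationProtocol:
    """3 and 10 mM lactate pulses followed by a terminal CO2/HCO3- pulse."""
    return ApplicationProtocol((
        SolutionEvent("lactate", 3.0, 120.0, 240.0),
        SolutionEvent("lactate", 10.0, 420.0, 540.0),
        SolutionEvent("CO2", 5.0, 840.0, 1080.0),
    ))


def make_trace(t, y, kind="pH", **meta) -> Trace:
    return Trace(np.asarray(t, float), np.asarray(y, float), kind, meta)
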