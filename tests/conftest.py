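import pytest

from coldshift import (
    RATES_14C,
    RATES_24C,
    ShiftProtocol,
    SteadyState,
    steady_state,
)


@pytest.fixture
def warm_rates():
    return RATES_24C


@pytest.fixture
def cold_rates():
    return RATES_14C


@pytest.fixture
def warm_ss() -> SteadyState:
    return steady_state(RATES_24C)


@pytest.fixture
def cold_ss() -> SteadyState:
    return steady_state(RATES_14C)


@pytest.fixture
def cold_shift_protocol() -> ShiftProtocol:
    """The canonical cold shift: warm rates until t=400, cold after."""
    return ShiftProtocol(RATES_24C, RATES_14C, shift_time=400.0,
                         duration=1200.0)
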