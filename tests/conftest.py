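import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from magstim.protocol import ProtocolPhase, StimulationProtocol


@pytest.fixture
def behavioral_protocol() -> StimulationProtocol:
    """The in vivo light-dark protocol: 30 s stim / 30 s rest, 10 Hz, x5."""
    return StimulationProtocol(
        phases=[
            ProtocolPhase(
                stim_duration=30,
                rest_duration=30,
                frequency=10,
                dead_time=0.001,
                mode="bidirectional",
                repeats=5,
            )
        ]
    )


@pytest.fixture
def short_protocol() -> StimulationProtocol:
    """Small protocol for fast controller runs: 5 s stim / 5 s rest, x2."""
    return StimulationProtocol(
        phases=[
            ProtocolPhase(
                stim_duration=5,
                rest_duration=5,
                frequency=10,
                dead_time=0.001,
                repeats=2,
            )
        ]
    )
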