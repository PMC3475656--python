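import numpy as np
import pytest

import spikebifurc as sb


@pytest.fixture(scope="session")
def frozen_h():
    """Default frozen-noise waveform: 1050 ms at 10 kHz, seed 0."""
    return sb.generate_frozen_noise(0, n_keep=10500)


@pytest.fixture(scope="session")
def wb_params():
    return sb.NeuronParams()


@pytest.fixture(scope="session")
def three_pattern_specs():
    """Three disjoint-event patterns, 1 ms jitter, reliability 0.9."""
    times = [[50.0, 150.0, 250.0], [80.0, 180.0, 280.0], [110.0, 210.0, 310.0]]
    return [
        sb.PatternSpec(
            event_times=t,
            event_reliabilities=[0.9] * 3,
            event_jitters=[1.0] * 3,
            occupation=1.0 / 3.0,
        )
        for t in times
    ]
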