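import numpy as np
import pytest

from erkpulse import PulseParams, PulseTrainSpec, Trace, TraceSpec, generate_trace


@pytest.fixture
def tspec():
    """Standard recording: 90 min at 1.5-min sampling, basal 1.0, sigma 0.01."""
    return TraceSpec()


@pytest.fixture
def flat_trace():
    t = np.arange(61) * 1.5
    return Trace(cell_id="flat", times=t, values=np.full(61, 1.25))


@pytest.fixture
def single_pulse_trace():
    """Noiseless basal-1 trace with one pulse A=0.1 at t=45, duration 20."""
    trace, truth = generate_trace(
        [PulseParams(amplitude=0.1, center=45.0, angular_freq=2 * np.pi / 20)],
        TraceSpec(noise_sd=0.0),
        seed=0,
    )
    return trace, truth


def make_noisy_trace(seed, noise_sd=0.01, pulses=(), basal=1.0):
    trace, _ = generate_trace(
        list(pulses),
        TraceSpec(basal=basal, noise_sd=noise_sd),
        seed=seed,
    )
    return trace
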