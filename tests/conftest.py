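import logging

import numpy as np
import pytest

from spinedyn.events import DetectionParams, FluorescenceTrace
from spinedyn.simulate import SimParams


@pytest.fixture(autouse=True)
def _quiet_matching_warnings(caplog):
    # crowding warnings are informative in production but noisy in bulk tests
    logging.getLogger("spinedyn.turnover").setLevel(logging.ERROR)
    yield
    logging.getLogger("spinedyn.turnover").setLevel(logging.NOTSET)


@pytest.fixture
def det_params() -> DetectionParams:
    return DetectionParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20261001)


def make_dff_trace(
    values: np.ndarray, frame_rate_hz: float = 12.0
) -> FluorescenceTrace:
    return FluorescenceTrace(np.asarray(values, dtype=float), frame_rate_hz, "dff")


def pulse_trace(
    n_frames: int,
    pulses: list[tuple[int, int, float]],
    noise_sd: float = 0.01,
    seed: int = 0,
) -> np.ndarray:
    """Baseline noise plus rectangular pulses (onset, length, amplitude)."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, noise_sd, size=n_frames)
    for onset, length, amp in pulses:
        x[onset : onset + length] += amp
    return x


@pytest.fixture
def quiet_sim_params() -> SimParams:
    """Short, silent recording: no events, no noise."""
    return SimParams(
        duration_s=30.0,
        shaft_event_rate_hz=0.0,
        spine_specific_rate_hz=0.0,
        noise_sd=0.0,
        n_spines_per_dendrite=3,
        seed=7,
    )
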