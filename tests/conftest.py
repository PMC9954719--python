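import numpy as np
import pytest

from rampulse.pulses import make_schedule
from rampulse.simulate import RecordingGroundTruth, ShapeEffect, simulate_recording


@pytest.fixture(scope="session")
def schedule():
    """The reference protocol: 20 levels, 3-31.5 nC, 32 reps at 4 Hz."""
    return make_schedule()


@pytest.fixture(scope="session")
def ground_truth():
    return RecordingGroundTruth(
        spont_rate_Hz=10.0, Rmax_Hz=60.0, Q50_nC=15.0, k_nC=2.0,
        latency_mean_ms=15.0, latency_sd_ms=2.0,
    )


@pytest.fixture(scope="session")
def sim_events(schedule, ground_truth):
    """One simulated recording under the rectangular reference shape."""
    return simulate_recording(
        ground_truth, ShapeEffect(), schedule, seed=12345,
        recording_id="r000", shape_id="Rec-C",
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(987)
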