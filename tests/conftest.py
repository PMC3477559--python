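import math
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from dynfc import (
    CouplingEvent,
    CouplingGroundTruth,
    build_fcg_series,
    generate_trials,
)

# study-scale conditions used by the recovery fixtures: 12 ROIs, 36 trials,
# one gamma-band coupling event at strength 1 and lag pi/2 spanning 100-300 ms
FS = 500.0
N_ROI = 12
N_SAMPLES = 400
N_TRIALS = 36
ONSET = 100
EVENT = dict(band_freq=35.0, phase_lag=math.pi / 2, strength=1.0, onset_ms=100.0, offset_ms=300.0)


@pytest.fixture(scope="session")
def coupled_dataset():
    """12-ROI dataset with one planted pair coupling (0, 1)."""
    truth = CouplingGroundTruth(
        events=(CouplingEvent(pair=(0, 1), **EVENT),), noise_sd=0.3, seed=11
    )
    return generate_trials(
        truth, N_ROI, N_SAMPLES, N_TRIALS, FS, onset_sample=ONSET
    ), truth


@pytest.fixture(scope="session")
def coupled_fcgs(coupled_dataset):
    dataset, _ = coupled_dataset
    return build_fcg_series(dataset, "gamma", measure="plv")


@pytest.fixture(scope="session")
def triangle_datasets():
    """Condition A: events (0→1) and (0→2) forming a coupled triangle; B: none."""
    events = (
        CouplingEvent(pair=(0, 1), **EVENT),
        CouplingEvent(pair=(0, 2), **{**EVENT, "phase_lag": math.pi / 4}),
    )
    a = generate_trials(
        CouplingGroundTruth(events=events, noise_sd=0.3, seed=21),
        N_ROI, N_SAMPLES, N_TRIALS, FS, onset_sample=ONSET,
    )
    b = generate_trials(
        CouplingGroundTruth(events=(), noise_sd=0.3, seed=22),
        N_ROI, N_SAMPLES, N_TRIALS, FS, onset_sample=ONSET,
    )
    return a, b


def in_window_mask(fcgs, onset_ms=EVENT["onset_ms"], offset_ms=EVENT["offset_ms"], fs=FS):
    """Latencies whose full window lies inside the coupling event."""
    half_ms = fcgs.window.half / fs * 1e3
    lat = fcgs.latencies_ms
    return (lat - half_ms >= onset_ms) & (lat + half_ms <= offset_ms)
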