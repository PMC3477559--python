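"""Band-pass filtering, instantaneous phase, and moving-window geometry.

The moving window follows the cycle criterion: its width covers ``cc``
cycles of the band's lowest frequency, ``w_l = (cc / f_low) * fs + 1``
samples, rounded to the nearest odd integer so the window is symmetric
about its center latency.  The window then advances by a fixed sample
step (5 samples by default downstream).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .simulate import TrialDataset

__all__ = [
    "BandSpec",
    "WindowSpec",
    "PhaseTensor",
    "BANDS",
    "window_length",
    "bandpass",
    "instantaneous_phase",
    "window_centers",
]


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band [f_low, f_high] in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_low < self.f_high):
            raise ValueError(
                f"band {self.name!r}: need 0 <= f_low < f_high, got "
                f"[{self.f_low}, {self.f_high}]"
            )

    def validate_against(self, fs: float) -> None:
        if self.f_high >= fs / 2:
            raise ValueError(
                f"band {self.name!r}: f_high {self.f_high} Hz is not below "
                f"the Nyquist frequency {fs / 2} Hz"
            )


#: Canonical EEG/MEG rhythm bands; "wide" is broadband with an effective
#: f_low of 1 Hz governing the window width.
BANDS: dict[str, BandSpec] = {
    "delta": BandSpec("delta", 1.0, 4.0),
    "theta": BandSpec("theta", 4.0, 8.0),
    "alpha": BandSpec("alpha", 8.0, 13.0),
    "beta": BandSpec("beta", 13.0, 30.0),
    "gamma": BandSpec("gamma", 30.0, 45.0),
    "wide": BandSpec("wide", 1.0, 45.0),
}


def get_band(band: "str | BandSpec") -> BandSpec:
    if isinstance(band, BandSpec):
        return band
    try:
        return BANDS[band]
    except KeyError:
        raise ValueError(f"unknown band {band!r}; known: {sorted(BANDS)}") from None


@dataclass(frozen=True)
class WindowSpec:
    """Moving-window geometry: cycle count, width in samples, and step."""

    cc: float
    w_l: int
    step: int

    def __post_init__(self) -> None:
        if self.w_l % 2 != 1:
            raise ValueError(f"w_l must be odd (symmetric window), got {self.w_l}")
        if self.step < 1:
            raise ValueError("step must be >= 1")

    @property
    def half(self) -> int:
        return self.w_l // 2

    @classmethod
    def from_band(cls, band: "str | BandSpec", fs: float, cc: float = 2.0, step: int = 5) -> "WindowSpec":
        return cls(cc=cc, w_l=window_length(get_band(band), fs, cc), step=step)


@dataclass
class PhaseTensor:
    """Instantaneous phases [n_roi × n_samples × n_trials], wrapped to (−π, π]."""

    phases: np.ndarray
    band: BandSpec | None = None

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.ndim != 3:
            raise ValueError("phases must be a 3-way array [n_roi × n_samples × n_trials]")


def window_length(band: "str | BandSpec", fs: float, cc: float = 2.0) -> int:
    """Cycle-criterion window width in samples: (cc / f_low) * fs + 1.

    Rounded to the nearest odd integer (ties round up) so the window is
    symmetric about its center sample.
    """
    band = get_band(band)
    if band.f_low <= 0:
        raise ValueError(
            "f_low must be positive: broadband analyses must declare an "
            "effective lower frequency"
        )
    if fs <= 2 * band.f_high:
        raise ValueError(f"fs={fs} Hz too low for band {band.name!r} (f_high={band.f_high})")
    if cc <= 0:
        raise ValueError("cc must be positive")
    w = (cc / band.f_low) * fs + 1.0
    return 2 * math.floor(w / 2.0) + 1


def bandpass(dataset: TrialDataset, band: "str | BandSpec", order: int = 4) -> TrialDataset:
    """Zero-phase Butterworth band-pass along the time axis.

    Forward-backward second-order-section filtering, so the output has no
    phase distortion and the same length as the input.
    """
    band = get_band(band)
    band.validate_against(dataset.fs)
    nyq = dataset.fs / 2.0
    wn = [band.f_low / nyq, band.f_high / nyq]
    sos = sps.butter(order, wn, btype="bandpass", output="sos")
    # a too-narrow band puts poles so close to the unit circle that the
    # filter transient outlasts the epoch; reject with a diagnostic
    _, poles, _ = sps.butter(order, wn, btype="bandpass", output="zpk")
    r = np.abs(poles).max()
    decay = math.inf if r >= 1.0 else -1.0 / math.log(r)
    if 3.0 * decay > dataset.n_samples:
        raise ValueError(
            f"band {band.name!r} too narrow for an order-{order} design at "
            f"fs={dataset.fs} Hz: filter transient (~{3 * decay:.0f} samples) "
            f"exceeds the epoch ({dataset.n_samples} samples)"
        )
    filtered = sps.sosfiltfilt(sos, dataset.signals, axis=1)
    return TrialDataset(
        signals=filtered,
        fs=dataset.fs,
        onset_sample=dataset.onset_sample,
        roi_labels=list(dataset.roi_labels),
        trial_conditions=list(dataset.trial_conditions),
    )


def instantaneous_phase(dataset: TrialDataset, band: BandSpec | None = None) -> PhaseTensor:
    """Phase of the analytic signal (Hilbert transform) per ROI and trial.

    The input is expected to be band-limited already.  A flat (all-zero)
    ROI/trial series has no defined phase and is rejected.
    """
    sig = dataset.signals
    flat = np.ptp(sig, axis=1) == 0
    if flat.any():
        roi, trial = np.argwhere(flat)[0]
        raise ValueError(
            f"instantaneous phase undefined for constant signal "
            f"(ROI {roi}, trial {trial})"
        )
    analytic = sps.hilbert(sig, axis=1)
    return PhaseTensor(phases=np.angle(analytic), band=band)


def window_centers(n_samples: int, w_l: int, step: int) -> np.ndarray:
    """0-based window-center sample indices; every window fits the epoch.

    Centers start at ``w_l // 2`` and advance by ``step``; latencies whose
    window would overrun the epoch are skipped, not padded.
    """
    if w_l > n_samples:
        raise ValueError(f"window length {w_l} exceeds epoch length {n_samples}")
    if w_l % 2 != 1:
        raise ValueError(f"w_l must be odd, got {w_l}")
    if step < 1:
        raise ValueError("step must be >= 1")
    half = w_l // 2
    return np.arange(half, n_samples - half, step)
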