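"""Synthetic multi-trial oscillator datasets with known pairwise phase coupling.

Each region of interest (ROI) carries a band-limited oscillation whose
carrier phase is redrawn uniformly on every trial, over additive noise.
A :class:`CouplingEvent` locks the phase of one ROI to another within a
latency window, so that across-trial phase-synchrony estimators applied
downstream have a known ground truth to recover.

The coupling mechanism is phase-driving: within the event window the
*second* ROI of the pair adopts the first ROI's per-trial phase minus
``phase_lag``, plus von-Mises jitter whose concentration grows with
``strength`` (strength 1 means zero jitter, strength 0 means a uniform,
i.e. uncoupled, phase).  This gives continuous control of the expected
phase-locking value between the chance level and 1.

Time convention: latencies are in milliseconds relative to stimulus onset;
sample indices are 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CouplingEvent",
    "CouplingGroundTruth",
    "TrialDataset",
    "generate_trials",
]


@dataclass(frozen=True)
class CouplingEvent:
    """A latency-localized pairwise phase-coupling episode.

    Parameters
    ----------
    pair
        ``(driver, driven)`` ROI indices; the driven ROI adopts the
        driver's phase (minus ``phase_lag``) inside the window.
    band_freq
        Carrier frequency in Hz of the coupled oscillation; both ROIs of
        the pair oscillate at this frequency.
    phase_lag
        Phase difference (radians) imposed between driver and driven ROI.
    strength
        Coupling strength in [0, 1]: the concentration of the across-trial
        phase-difference distribution increases monotonically in strength.
    onset_ms, offset_ms
        Event window in milliseconds relative to stimulus onset.
    """

    pair: tuple[int, int]
    band_freq: float
    phase_lag: float
    strength: float
    onset_ms: float
    offset_ms: float

    def __post_init__(self) -> None:
        u, v = self.pair
        if u == v:
            raise ValueError(f"coupling pair must be two distinct ROIs, got {self.pair}")
        if not (self.onset_ms < self.offset_ms):
            raise ValueError(
                f"event {self.pair}: onset_ms ({self.onset_ms}) must precede "
                f"offset_ms ({self.offset_ms})"
            )
        if not (0.0 <= self.strength <= 1.0):
            raise ValueError(f"event {self.pair}: strength must be in [0, 1], got {self.strength}")
        if self.band_freq <= 0:
            raise ValueError(f"event {self.pair}: band_freq must be positive")

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "band_freq": self.band_freq,
            "phase_lag": self.phase_lag,
            "strength": self.strength,
            "onset_ms": self.onset_ms,
            "offset_ms": self.offset_ms,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CouplingEvent":
        return cls(
            pair=(int(d["pair"][0]), int(d["pair"][1])),
            band_freq=float(d["band_freq"]),
            phase_lag=float(d["phase_lag"]),
            strength=float(d["strength"]),
            onset_ms=float(d["onset_ms"]),
            offset_ms=float(d["offset_ms"]),
        )


@dataclass(frozen=True)
class CouplingGroundTruth:
    """The generator's full coupling schedule; identical seed → identical data."""

    events: tuple[CouplingEvent, ...] = ()
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def to_dict(self) -> dict:
        return {
            "events": [e.to_dict() for e in self.events],
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CouplingGroundTruth":
        return cls(
            events=tuple(CouplingEvent.from_dict(e) for e in d.get("events", [])),
            noise_sd=float(d.get("noise_sd", 0.5)),
            seed=int(d.get("seed", 0)),
        )


@dataclass
class TrialDataset:
    """Multi-trial ROI time series: signals[n_roi, n_samples, n_trials].

    ``onset_sample`` marks stimulus onset (0-based sample index), so the
    time axis in milliseconds is ``(arange(n_samples) - onset_sample) / fs * 1e3``.
    """

    signals: np.ndarray
    fs: float
    onset_sample: int
    roi_labels: list[str] = field(default_factory=list)
    trial_conditions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 3:
            raise ValueError(
                f"signals must be a 3-way array [n_roi × n_samples × n_trials], "
                f"got ndim={self.signals.ndim}"
            )
        n_roi, n_samples, n_trials = self.signals.shape
        if n_roi < 2:
            raise ValueError(f"need at least 2 ROIs, got {n_roi}")
        if n_trials < 2:
            raise ValueError(f"need at least 2 trials, got {n_trials}")
        if not (0 <= self.onset_sample < n_samples):
            raise ValueError(
                f"onset_sample {self.onset_sample} outside [0, {n_samples})"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("signals contain non-finite values")
        if not self.roi_labels:
            self.roi_labels = [f"roi{i}" for i in range(n_roi)]
        if len(self.roi_labels) != n_roi:
            raise ValueError(
                f"roi_labels length {len(self.roi_labels)} != n_roi {n_roi}"
            )
        if not self.trial_conditions:
            self.trial_conditions = ["A"] * n_trials
        if len(self.trial_conditions) != n_trials:
            raise ValueError(
                f"trial_conditions length {len(self.trial_conditions)} != "
                f"n_trials {n_trials}"
            )

    @property
    def n_roi(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def n_trials(self) -> int:
        return self.signals.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Sample latencies in ms relative to stimulus onset."""
        return (np.arange(self.n_samples) - self.onset_sample) / self.fs * 1e3


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _event_gate(times_ms: np.ndarray, onset: float, offset: float, taper_ms: float) -> np.ndarray:
    """0→1→0 gate: smoothstep ramps of taper_ms just outside [onset, offset]."""
    if taper_ms <= 0:
        return ((times_ms >= onset) & (times_ms <= offset)).astype(float)
    rise = _smoothstep((times_ms - (onset - taper_ms)) / taper_ms)
    fall = _smoothstep(((offset + taper_ms) - times_ms) / taper_ms)
    return np.minimum(rise, fall)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], sd: float) -> np.ndarray:
    """1/f-amplitude noise along the last axis, scaled to standard deviation sd."""
    white = rng.standard_normal(shape)
    spectrum = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1])
    freqs[0] = freqs[1] if len(freqs) > 1 else 1.0
    spectrum /= np.sqrt(freqs)
    out = np.fft.irfft(spectrum, n=shape[-1], axis=-1)
    std = out.std()
    return out * (sd / std) if std > 0 else out


def _jitter_kappa(strength: float, kappa0: float) -> float:
    # monotone map: s=0 -> 0 (uniform), s->1 -> inf (point mass)
    return kappa0 * strength / (1.0 - strength)


def generate_trials(
    truth: CouplingGroundTruth,
    n_roi: int,
    n_samples: int,
    n_trials: int,
    fs: float,
    *,
    onset_sample: int | None = None,
    carrier_freq: float = 10.0,
    amplitude: float = 1.0,
    taper_ms: float = 20.0,
    jitter_kappa0: float = 8.0,
    pink: bool = False,
    roi_labels: list[str] | None = None,
    trial_conditions: list[str] | None = None,
) -> TrialDataset:
    """Simulate band-limited oscillatory trials with planted phase coupling.

    Every ROI oscillates at ``carrier_freq`` Hz (ROIs taking part in a
    coupling event oscillate at that event's ``band_freq``) with a fresh
    uniform phase on each trial, plus additive white (or pink) noise of
    standard deviation ``truth.noise_sd``.  Inside an event window the
    driven ROI's phase is pulled onto the driver's phase minus the event's
    lag, with smooth on/off ramps so no amplitude discontinuity is
    introduced.

    Parameters
    ----------
    truth
        Coupling schedule, noise level and seed.
    onset_sample
        Stimulus-onset sample; defaults to ``n_samples // 4``.
    taper_ms
        Half-cosine-like ramp duration applied just outside each event
        window to keep the phase trajectory continuous.
    jitter_kappa0
        Scale of the strength → von-Mises-concentration map
        ``kappa = jitter_kappa0 * s / (1 - s)``.

    Raises
    ------
    ValueError
        If an event's pair indices exceed ``n_roi``, its window falls
        outside the epoch, or two events drive the same ROI in
        overlapping windows.
    """
    if min(n_roi, n_samples, n_trials) <= 0 or fs <= 0:
        raise ValueError("n_roi, n_samples, n_trials and fs must be positive")
    if onset_sample is None:
        onset_sample = n_samples // 4

    times_ms = (np.arange(n_samples) - onset_sample) / fs * 1e3
    t_sec = times_ms / 1e3

    driven_windows: dict[int, list[tuple[float, float]]] = {}
    for ev in truth.events:
        u, v = ev.pair
        if max(u, v) >= n_roi or min(u, v) < 0:
            raise ValueError(f"event {ev.pair}: ROI index out of range for n_roi={n_roi}")
        if ev.onset_ms < times_ms[0] or ev.offset_ms > times_ms[-1]:
            raise ValueError(
                f"event {ev.pair} window [{ev.onset_ms}, {ev.offset_ms}] ms lies "
                f"outside the epoch [{times_ms[0]:.1f}, {times_ms[-1]:.1f}] ms"
            )
        for lo, hi in driven_windows.get(v, []):
            if ev.onset_ms < hi and lo < ev.offset_ms:
                raise ValueError(
                    f"event {ev.pair}: overlapping events driving ROI {v} are not supported"
                )
        driven_windows.setdefault(v, []).append((ev.onset_ms, ev.offset_ms))

    rng = np.random.default_rng(truth.seed)
    theta = rng.uniform(-math.pi, math.pi, size=(n_roi, n_trials))

    freqs = np.full(n_roi, float(carrier_freq))
    for ev in truth.events:
        freqs[list(ev.pair)] = ev.band_freq

    # phase-offset trajectory per (roi, trial, time); starts flat at theta
    offset = np.broadcast_to(theta[:, :, None], (n_roi, n_trials, n_samples)).copy()

    for ev in truth.events:
        u, v = ev.pair
        if ev.strength >= 1.0:
            jitter = np.zeros(n_trials)
        else:
            kappa = _jitter_kappa(ev.strength, jitter_kappa0)
            if kappa <= 0:
                jitter = rng.uniform(-math.pi, math.pi, size=n_trials)
            else:
                jitter = rng.vonmises(0.0, kappa, size=n_trials)
        target = theta[u] - ev.phase_lag + jitter
        # shortest-arc move from the baseline phase to the coupled phase
        delta = np.angle(np.exp(1j * (target - theta[v])))
        gate = _event_gate(times_ms, ev.onset_ms, ev.offset_ms, taper_ms)
        offset[v] = theta[v][:, None] + gate[None, :] * delta[:, None]

    carrier = 2.0 * math.pi * freqs[:, None, None] * t_sec[None, None, :]
    signals = amplitude * np.cos(carrier + offset)

    if truth.noise_sd > 0:
        if pink:
            signals = signals + _pink_noise(rng, signals.shape, truth.noise_sd)
        else:
            signals = signals + rng.normal(0.0, truth.noise_sd, size=signals.shape)

    # generator works in (roi, trial, time); dataset stores (roi, time, trial)
    return TrialDataset(
        signals=np.transpose(signals, (0, 2, 1)),
        fs=fs,
        onset_sample=onset_sample,
        roi_labels=roi_labels or [],
        trial_conditions=trial_conditions or [],
    )
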