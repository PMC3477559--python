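"""Latency-resolved across-trial phase synchrony and trimmed graph series.

For a pair of ROIs (u, v) with instantaneous phases φᵘ(n, k), φᵛ(n, k)
(latency n, trial k) and phase difference Δφ = φᵘ − φᵛ, the two
estimators at window center n are

    PLV(n) = (1 / N_trials) | Σ_k (1 / W_L) Σ_{n'∈win(n)} exp(i Δφ(n', k)) |
    PLI(n) = | (1 / (N_trials W_L)) Σ_k Σ_{n'∈win(n)} sign(sin Δφ(n', k)) |

both in [0, 1].  PLV measures the across-trial (and within-window)
consistency of the phase difference; PLI measures only the asymmetry of
its distribution about 0 mod π, so zero-lag (volume-conduction-like)
coupling yields PLI = 0 while PLV = 1.

Each value gets a Rayleigh-test significance p = exp(−N_trials · SM²)
(SM the synchrony value) and the N(N−1)/2 pairwise tests at each latency
are trimmed by Benjamini–Hochberg FDR at level q; surviving values fill
the weighted adjacency matrix W of that latency's functional
connectivity graph (FCG).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .simulate import TrialDataset
from .spectral import (
    BandSpec,
    PhaseTensor,
    WindowSpec,
    bandpass,
    get_band,
    instantaneous_phase,
    window_centers,
)

__all__ = [
    "SyncTimeSeries",
    "FCGSeries",
    "plv_timecourse",
    "pli_timecourse",
    "pairwise_sync",
    "rayleigh_pvalue",
    "fdr_trim",
    "build_fcg_series",
]


@dataclass
class SyncTimeSeries:
    """Pairwise synchrony values [n_pairs × n_latencies] in [0, 1]."""

    measure: str
    values: np.ndarray
    latencies_ms: np.ndarray
    pairs: np.ndarray  # [n_pairs, 2] upper-triangle (u, v), u < v
    band: BandSpec | None = None


@dataclass
class FCGSeries:
    """A latency-indexed series of trimmed, weighted adjacency matrices.

    ``adjacency[t]`` is the symmetric non-negative matrix W at latency
    ``latencies_ms[t]``: synchrony values where significant after FDR
    trimming, 0 elsewhere (and on the diagonal).  ``raw`` keeps the
    untrimmed values; ``pvalues`` the Rayleigh significances.
    """

    adjacency: np.ndarray  # [n_lat, N, N]
    significance: np.ndarray  # bool, same shape
    raw: np.ndarray  # untrimmed synchrony values, same shape
    pvalues: np.ndarray  # same shape, diagonal = 1
    latencies_ms: np.ndarray
    centers: np.ndarray  # window-center sample indices
    measure: str = "plv"
    band: BandSpec | None = None
    window: WindowSpec | None = None
    q: float = 0.001
    roi_labels: list[str] = field(default_factory=list)

    @property
    def n_latencies(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_roi(self) -> int:
        return self.adjacency.shape[1]


def _check_phases(phases_u: np.ndarray, phases_v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pu = np.asarray(phases_u, dtype=float)
    pv = np.asarray(phases_v, dtype=float)
    if pu.shape != pv.shape or pu.ndim != 2:
        raise ValueError("phase arrays must share shape [n_samples × n_trials]")
    if pu.shape[1] < 2:
        raise ValueError("need at least 2 trials")
    if not (np.isfinite(pu).all() and np.isfinite(pv).all()):
        raise ValueError("phases contain NaN or infinite values")
    return pu, pv


def _window_mean(per_sample: np.ndarray, window: WindowSpec, n_trials: int,
                 centers: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Mean over window samples and trials of a per-sample trial sum.

    ``per_sample`` is the trial-summed statistic at each sample (complex
    for PLV, real for PLI); returns (|mean| per center, centers).
    """
    n_samples = per_sample.shape[0]
    if centers is None:
        centers = window_centers(n_samples, window.w_l, window.step)
    half = window.half
    cs = np.concatenate([[0], np.cumsum(per_sample, axis=0)])
    sums = cs[centers + half + 1] - cs[centers - half]
    return np.abs(sums) / (window.w_l * n_trials), centers


def plv_timecourse(
    phases_u: np.ndarray,
    phases_v: np.ndarray,
    window: WindowSpec,
    centers: np.ndarray | None = None,
) -> np.ndarray:
    """Across-trial phase-locking value at each window center.

    ``phases_u``, ``phases_v``: [n_samples × n_trials] instantaneous
    phases of the two ROIs.
    """
    pu, pv = _check_phases(phases_u, phases_v)
    z = np.exp(1j * (pu - pv)).sum(axis=1)
    values, _ = _window_mean(z, window, pu.shape[1], centers)
    return values


def pli_timecourse(
    phases_u: np.ndarray,
    phases_v: np.ndarray,
    window: WindowSpec,
    centers: np.ndarray | None = None,
) -> np.ndarray:
    """Across-trial phase-lag index at each window center.

    The absolute value is taken around the full double (trial × window)
    sum of sign(sin Δφ), so a phase difference symmetric about 0 mod π
    cancels to 0 while a consistently one-sided lag gives 1.
    """
    pu, pv = _check_phases(phases_u, phases_v)
    s = np.sign(np.sin(pu - pv)).sum(axis=1)
    values, _ = _window_mean(s, window, pu.shape[1], centers)
    return values


_MEASURES = {"plv": plv_timecourse, "pli": pli_timecourse}


def pairwise_sync(
    phases: PhaseTensor,
    window: WindowSpec,
    measure: str = "plv",
    latencies_ms: np.ndarray | None = None,
) -> SyncTimeSeries:
    """Synchrony time course for every unordered ROI pair."""
    measure = measure.lower()
    if measure not in _MEASURES:
        raise ValueError(f"measure must be one of {sorted(_MEASURES)}, got {measure!r}")
    p = phases.phases
    n_roi, n_samples, n_trials = p.shape
    centers = window_centers(n_samples, window.w_l, window.step)
    iu, iv = np.triu_indices(n_roi, k=1)
    func = _MEASURES[measure]
    values = np.empty((iu.size, centers.size))
    for idx, (u, v) in enumerate(zip(iu, iv)):
        values[idx] = func(p[u], p[v], window, centers)
    if latencies_ms is None:
        latencies_ms = centers.astype(float)
    else:
        latencies_ms = np.asarray(latencies_ms, dtype=float)[centers]
    return SyncTimeSeries(
        measure=measure,
        values=values,
        latencies_ms=latencies_ms,
        pairs=np.column_stack([iu, iv]),
        band=phases.band,
    )


def rayleigh_pvalue(sm: "float | np.ndarray", n_trials: int) -> "float | np.ndarray":
    """Rayleigh-test significance of a synchrony value: exp(−n_trials · sm²)."""
    sm_arr = np.asarray(sm, dtype=float)
    if np.any((sm_arr < 0) | (sm_arr > 1)):
        raise ValueError("synchrony values must lie in [0, 1]")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    p = np.clip(np.exp(-n_trials * sm_arr**2), 0.0, 1.0)
    return float(p) if np.isscalar(sm) else p


def fdr_trim(pvalues: np.ndarray, q: float = 0.001) -> np.ndarray:
    """Benjamini–Hochberg step-up mask over a family of p-values.

    Returns a boolean array, True = significant at FDR level q.
    """
    p = np.asarray(pvalues, dtype=float)
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    if p.size == 0:
        return np.zeros(p.shape, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape)


def build_fcg_series(
    dataset: TrialDataset,
    band: "str | BandSpec",
    measure: str = "plv",
    *,
    cc: float = 2.0,
    step: int = 5,
    q: float = 0.001,
    window: WindowSpec | None = None,
    filter_order: int = 4,
) -> FCGSeries:
    """Full band → phase → synchrony → trim pipeline for one dataset.

    Band-passes the data, extracts Hilbert phases, evaluates the chosen
    synchrony measure for every pair at every window center, computes
    Rayleigh p-values, applies BH trimming per latency across the
    N(N−1)/2 pairs, and assembles the trimmed adjacency series.
    """
    band = get_band(band)
    if window is None:
        window = WindowSpec.from_band(band, dataset.fs, cc=cc, step=step)
    filtered = bandpass(dataset, band, order=filter_order)
    phases = instantaneous_phase(filtered, band=band)
    sync = pairwise_sync(phases, window, measure=measure, latencies_ms=dataset.times_ms)

    n_trials = dataset.n_trials
    n_roi = dataset.n_roi
    pvals = rayleigh_pvalue(sync.values, n_trials)
    sig = np.empty_like(sync.values, dtype=bool)
    for t in range(sync.values.shape[1]):
        sig[:, t] = fdr_trim(pvals[:, t], q=q)

    n_lat = sync.values.shape[1]
    iu, iv = sync.pairs[:, 0], sync.pairs[:, 1]
    raw = np.zeros((n_lat, n_roi, n_roi))
    pmat = np.ones((n_lat, n_roi, n_roi))
    smat = np.zeros((n_lat, n_roi, n_roi), dtype=bool)
    raw[:, iu, iv] = sync.values.T
    raw[:, iv, iu] = sync.values.T
    pmat[:, iu, iv] = pvals.T
    pmat[:, iv, iu] = pvals.T
    smat[:, iu, iv] = sig.T
    smat[:, iv, iu] = sig.T
    adjacency = np.where(smat, raw, 0.0)

    return FCGSeries(
        adjacency=adjacency,
        significance=smat,
        raw=raw,
        pvalues=pmat,
        latencies_ms=sync.latencies_ms,
        centers=window_centers(dataset.n_samples, window.w_l, window.step),
        measure=measure.lower(),
        band=band,
        window=window,
        q=q,
        roi_labels=list(dataset.roi_labels),
    )
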