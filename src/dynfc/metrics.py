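"""Weighted local efficiency of FCGs and between-condition contrasts.

Local efficiency (LE) of a weighted graph W:

    LE = (1/N) Σ_i [ Σ_{j≠h ∈ G_i} 1 / d_jh ] / (k_i (k_i − 1))

where G_i is the subgraph induced by node i's neighbors, k_i its degree,
and d_jh the shortest path length between j and h *within* G_i, using
edge lengths 1/w (synchrony weights in [0, 1] map to lengths ≥ 1, so
0 ≤ LE ≤ 1).  Nodes with fewer than two neighbors contribute 0, and
unreachable pairs contribute 0 inverse distance — the fault-tolerance
reading: LE measures how well a node's neighborhood communicates when
the node itself is removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .connectivity import FCGSeries

__all__ = [
    "MetricTimeSeries",
    "local_efficiency",
    "le_timecourse",
    "condition_contrast",
    "average_series",
]


@dataclass
class MetricTimeSeries:
    """A scalar network metric per latency."""

    latencies_ms: np.ndarray
    values: np.ndarray
    metric: str = "local_efficiency"
    band: str | None = None
    measure: str | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        self.latencies_ms = np.asarray(self.latencies_ms, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.latencies_ms.shape != self.values.shape:
            raise ValueError("latencies and values must align")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("metric values must be finite")


def _validate_adjacency(W: np.ndarray, atol: float = 1e-10) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("adjacency must be square")
    if np.any(W < 0):
        raise ValueError("adjacency weights must be non-negative")
    if not np.allclose(W, W.T, atol=atol):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.abs(np.diag(W)) > atol):
        raise ValueError("adjacency diagonal must be zero")
    return W


def local_efficiency(W: np.ndarray) -> float:
    """Weighted local efficiency of a symmetric non-negative adjacency."""
    W = _validate_adjacency(W)
    n = W.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(W[i] > 0)
        k = nbrs.size
        if k < 2:
            continue
        sub = W[np.ix_(nbrs, nbrs)]
        lengths = np.zeros_like(sub)
        nz = sub > 0
        lengths[nz] = 1.0 / sub[nz]
        d = shortest_path(csr_matrix(lengths), method="D", directed=False)
        off = ~np.eye(k, dtype=bool)
        finite = off & np.isfinite(d)
        inv = np.zeros_like(d)
        inv[finite] = 1.0 / d[finite]
        total += inv.sum() / (k * (k - 1))
    return total / n


def le_timecourse(fcgs: FCGSeries, condition: str | None = None) -> MetricTimeSeries:
    """Local efficiency of each latency's trimmed FCG."""
    values = np.array([local_efficiency(W) for W in fcgs.adjacency])
    return MetricTimeSeries(
        latencies_ms=fcgs.latencies_ms,
        values=values,
        metric="local_efficiency",
        band=fcgs.band.name if fcgs.band is not None else None,
        measure=fcgs.measure,
        condition=condition,
    )


def average_series(series: "list[MetricTimeSeries]") -> MetricTimeSeries:
    """Pointwise average of aligned metric series (e.g. over stimulus sides)."""
    if not series:
        raise ValueError("need at least one series")
    first = series[0]
    for s in series[1:]:
        if not np.array_equal(s.latencies_ms, first.latencies_ms):
            raise ValueError("series latencies are not aligned")
    return MetricTimeSeries(
        latencies_ms=first.latencies_ms,
        values=np.mean([s.values for s in series], axis=0),
        metric=first.metric,
        band=first.band,
        measure=first.measure,
        condition=first.condition,
    )


def condition_contrast(
    a: "MetricTimeSeries | list[MetricTimeSeries]",
    b: "MetricTimeSeries | list[MetricTimeSeries]",
) -> MetricTimeSeries:
    """Pointwise metric difference a − b between two conditions.

    Lists are averaged first (e.g. runs for left- and right-field
    stimuli) before differencing.
    """
    if isinstance(a, (list, tuple)):
        a = average_series(list(a))
    if isinstance(b, (list, tuple)):
        b = average_series(list(b))
    if not np.array_equal(a.latencies_ms, b.latencies_ms):
        raise ValueError("condition contrast requires aligned latencies")
    return MetricTimeSeries(
        latencies_ms=a.latencies_ms,
        values=a.values - b.values,
        metric=a.metric,
        band=a.band,
        measure=a.measure,
        condition=f"{a.condition or 'a'}-{b.condition or 'b'}",
    )
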