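"""End-to-end orchestration: dataset → FCG series → metrics, partitions, timelines.

A :class:`RunConfig` collects the analysis parameters (bands, synchrony
measure, cycle criterion, window step, FDR level, strongest-edge
fraction, seed) and :func:`run_pipeline` executes every stage per band,
returning an in-memory bundle plus a machine-readable manifest for
reproducibility.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import statsmodels

from . import __version__
from .clustering import ClusterTimeline, Partition, dominant_timeline, partition, top_k_edges
from .connectivity import FCGSeries, build_fcg_series
from .io import write_fcg_series, write_metric_series
from .metrics import MetricTimeSeries, le_timecourse
from .simulate import TrialDataset
from .spectral import BandSpec, get_band

__all__ = ["RunConfig", "BandResult", "run_pipeline"]

log = logging.getLogger("dynfc")


@dataclass
class RunConfig:
    """Analysis parameters for a full pipeline run."""

    bands: list = field(default_factory=lambda: ["alpha"])
    measure: str = "plv"
    cc: float = 2.0
    step: int = 5
    q: float = 0.001
    k_percent: float = 5.0
    seed: int | None = None
    filter_order: int = 4

    def __post_init__(self) -> None:
        if self.measure.lower() not in {"plv", "pli"}:
            raise ValueError(f"measure must be 'plv' or 'pli', got {self.measure!r}")
        if not (0 < self.q < 1):
            raise ValueError("q must be in (0, 1)")
        if not (0 < self.k_percent <= 100):
            raise ValueError("k_percent must be in (0, 100]")
        self.bands = [get_band(b) for b in self.bands]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bands"] = [dataclasses.asdict(b) for b in self.bands]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        bands = d.get("bands", ["alpha"])
        d["bands"] = [b if isinstance(b, str) else BandSpec(**b) for b in bands]
        return cls(**d)


@dataclass
class BandResult:
    """All per-band outputs of one pipeline run."""

    band: BandSpec
    fcgs: FCGSeries
    le: MetricTimeSeries
    partitions: list  # Partition per latency (None where the FCG is empty)
    timeline: ClusterTimeline
    top_edges: list  # per latency: list of (u, v, w)


def _manifest(config: RunConfig, dataset: TrialDataset) -> dict:
    return {
        "config": config.to_dict(),
        "dataset": {
            "n_roi": dataset.n_roi,
            "n_samples": dataset.n_samples,
            "n_trials": dataset.n_trials,
            "fs": dataset.fs,
            "onset_sample": int(dataset.onset_sample),
        },
        "versions": {
            "dynfc": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }


def run_pipeline(dataset: TrialDataset, config: RunConfig) -> dict:
    """Run every analysis stage for every configured band.

    Returns ``{"results": {band_name: BandResult}, "manifest": dict}``.
    Fully deterministic for a fixed config (the replicator dynamics use
    the deterministic barycenter initialization).
    """
    results: dict[str, BandResult] = {}
    for band in config.bands:
        t0 = time.perf_counter()
        log.info("band %s: building %s FCG series", band.name, config.measure)
        fcgs = build_fcg_series(
            dataset,
            band,
            measure=config.measure,
            cc=config.cc,
            step=config.step,
            q=config.q,
            filter_order=config.filter_order,
        )
        log.info("band %s: local efficiency over %d latencies", band.name, fcgs.n_latencies)
        le = le_timecourse(fcgs)
        partitions: list = []
        edges: list = []
        for t in range(fcgs.n_latencies):
            W = fcgs.adjacency[t]
            partitions.append(partition(W) if W.sum() > 0 else None)
            edges.append(top_k_edges(W, fcgs.significance[t], config.k_percent))
        timeline = dominant_timeline(fcgs)
        log.info("band %s: done in %.2f s", band.name, time.perf_counter() - t0)
        results[band.name] = BandResult(
            band=band,
            fcgs=fcgs,
            le=le,
            partitions=partitions,
            timeline=timeline,
            top_edges=edges,
        )
    return {"results": results, "manifest": _manifest(config, dataset)}


def write_bundle(bundle: dict, out_dir: "str | Path") -> Path:
    """Persist a pipeline bundle: per-band tables/arrays plus the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(json.dumps(bundle["manifest"], indent=1))
    for name, res in bundle["results"].items():
        write_fcg_series(res.fcgs, out / f"fcg_{name}")
        write_metric_series(res.le, out / f"le_{name}")
        labels = np.array(
            [
                p.labels if p is not None else np.zeros(res.fcgs.n_roi, dtype=int)
                for p in res.partitions
            ]
        )
        pd.DataFrame(
            labels,
            columns=res.fcgs.roi_labels or None,
        ).assign(latency_ms=res.fcgs.latencies_ms).to_csv(
            out / f"partitions_{name}.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            res.timeline.membership.T.astype(int),
            columns=res.fcgs.roi_labels or None,
        ).assign(latency_ms=res.timeline.latencies_ms).to_csv(
            out / f"timeline_{name}.tsv", sep="\t", index=False
        )
        rows = [
            {"latency_ms": lat, "roi_u": u, "roi_v": v, "weight": w}
            for lat, lst in zip(res.fcgs.latencies_ms, res.top_edges)
            for (u, v, w) in lst
        ]
        pd.DataFrame(rows, columns=["latency_ms", "roi_u", "roi_v", "weight"]).to_csv(
            out / f"edges_{name}.tsv", sep="\t", index=False
        )
    return out
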