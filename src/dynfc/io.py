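"""Readers and writers for trial datasets, FCG series, and metric tables.

On-disk layout (no standard exists for FCG series, so plain auditable
formats are used throughout):

* trial dataset  → ``<base>.npz`` (signals tensor) + ``<base>.json``
  sidecar with fs, onset_sample, roi_labels, trial_conditions and,
  when available, the generator's coupling ground truth;
* FCG series     → ``<base>.tsv`` long table (latency_ms, roi_u, roi_v,
  value, p, significant) + ``<base>.npz`` adjacency dump +
  ``<base>.json`` header (measure, band, window, q);
* metric series  → ``<base>.tsv`` + ``<base>.json`` header.

All writers round-trip: reading back yields an equal in-memory object.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import FCGSeries
from .metrics import MetricTimeSeries
from .simulate import CouplingGroundTruth, TrialDataset
from .spectral import BandSpec, WindowSpec

__all__ = [
    "write_trial_dataset",
    "read_trial_dataset",
    "write_fcg_series",
    "read_fcg_series",
    "write_metric_series",
    "read_metric_series",
]


def _base(path: "str | Path") -> Path:
    p = Path(path)
    return p.with_suffix("") if p.suffix in {".npz", ".json", ".tsv"} else p


def write_trial_dataset(
    dataset: TrialDataset,
    path: "str | Path",
    truth: CouplingGroundTruth | None = None,
) -> Path:
    base = _base(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(base.with_suffix(".npz"), signals=dataset.signals)
    sidecar = {
        "fs": dataset.fs,
        "onset_sample": int(dataset.onset_sample),
        "roi_labels": list(dataset.roi_labels),
        "trial_conditions": list(dataset.trial_conditions),
    }
    if truth is not None:
        sidecar["truth"] = truth.to_dict()
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return base


def read_trial_dataset(path: "str | Path") -> TrialDataset:
    """Load a dataset written by :func:`write_trial_dataset`.

    Raises a clear error naming any missing or invalid sidecar field.
    """
    base = _base(path)
    npz_path, json_path = base.with_suffix(".npz"), base.with_suffix(".json")
    if not npz_path.exists():
        raise FileNotFoundError(f"missing array container {npz_path}")
    if not json_path.exists():
        raise FileNotFoundError(f"missing JSON sidecar {json_path}")
    sidecar = json.loads(json_path.read_text())
    for field in ("fs", "onset_sample"):
        if field not in sidecar:
            raise ValueError(f"sidecar {json_path} missing required field {field!r}")
    with np.load(npz_path) as npz:
        if "signals" not in npz:
            raise ValueError(f"{npz_path} missing 'signals' array")
        signals = npz["signals"]
    return TrialDataset(
        signals=signals,
        fs=float(sidecar["fs"]),
        onset_sample=int(sidecar["onset_sample"]),
        roi_labels=list(sidecar.get("roi_labels", [])),
        trial_conditions=list(sidecar.get("trial_conditions", [])),
    )


def read_ground_truth(path: "str | Path") -> CouplingGroundTruth | None:
    """Recover the coupling schedule from a dataset sidecar, if present."""
    sidecar = json.loads(_base(path).with_suffix(".json").read_text())
    if "truth" not in sidecar:
        return None
    return CouplingGroundTruth.from_dict(sidecar["truth"])


def fcg_long_table(fcgs: FCGSeries) -> pd.DataFrame:
    """Long-format edge table of an FCG series (upper triangle only)."""
    n = fcgs.n_roi
    iu, iv = np.triu_indices(n, k=1)
    rows = []
    for t, lat in enumerate(fcgs.latencies_ms):
        rows.append(
            pd.DataFrame(
                {
                    "latency_ms": lat,
                    "roi_u": iu,
                    "roi_v": iv,
                    "value": fcgs.raw[t, iu, iv],
                    "p": fcgs.pvalues[t, iu, iv],
                    "significant": fcgs.significance[t, iu, iv],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_fcg_series(fcgs: FCGSeries, path: "str | Path") -> Path:
    base = _base(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    fcg_long_table(fcgs).to_csv(base.with_suffix(".tsv"), sep="\t", index=False)
    np.savez_compressed(
        base.with_suffix(".npz"),
        adjacency=fcgs.adjacency,
        significance=fcgs.significance,
        raw=fcgs.raw,
        pvalues=fcgs.pvalues,
        latencies_ms=fcgs.latencies_ms,
        centers=fcgs.centers,
    )
    header = {
        "measure": fcgs.measure,
        "band": dataclasses.asdict(fcgs.band) if fcgs.band else None,
        "window": dataclasses.asdict(fcgs.window) if fcgs.window else None,
        "q": fcgs.q,
        "roi_labels": list(fcgs.roi_labels),
    }
    base.with_suffix(".json").write_text(json.dumps(header, indent=1))
    return base


def read_fcg_series(path: "str | Path") -> FCGSeries:
    base = _base(path)
    header = json.loads(base.with_suffix(".json").read_text())
    with np.load(base.with_suffix(".npz")) as npz:
        arrays = {k: npz[k] for k in npz.files}
    return FCGSeries(
        adjacency=arrays["adjacency"],
        significance=arrays["significance"],
        raw=arrays["raw"],
        pvalues=arrays["pvalues"],
        latencies_ms=arrays["latencies_ms"],
        centers=arrays["centers"],
        measure=header["measure"],
        band=BandSpec(**header["band"]) if header.get("band") else None,
        window=WindowSpec(**header["window"]) if header.get("window") else None,
        q=header["q"],
        roi_labels=list(header.get("roi_labels", [])),
    )


def write_metric_series(series: MetricTimeSeries, path: "str | Path") -> Path:
    base = _base(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"latency_ms": series.latencies_ms, "value": series.values}).to_csv(
        base.with_suffix(".tsv"), sep="\t", index=False
    )
    header = {
        "metric": series.metric,
        "band": series.band,
        "measure": series.measure,
        "condition": series.condition,
    }
    base.with_suffix(".json").write_text(json.dumps(header, indent=1))
    return base


def read_metric_series(path: "str | Path") -> MetricTimeSeries:
    base = _base(path)
    table = pd.read_csv(base.with_suffix(".tsv"), sep="\t")
    header = json.loads(base.with_suffix(".json").read_text())
    return MetricTimeSeries(
        latencies_ms=table["latency_ms"].to_numpy(),
        values=table["value"].to_numpy(),
        metric=header.get("metric", "local_efficiency"),
        band=header.get("band"),
        measure=header.get("measure"),
        condition=header.get("condition"),
    )
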