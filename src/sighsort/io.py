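"""Plain-text I/O: traces, label tables, burst tables, ROI matrices, priors.

Everything is tab-delimited text with a small YAML sidecar for metadata
(sampling rate, units, seed, generator parameters), chosen over binary
stores for auditability.  Floats are written with a fixed ``%.10g`` format
so repeated runs of deterministic stages are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calcium import ROIMatrix
from .synthetic import EventLabel, SynthParams
from .trace import Trace

__all__ = [
    "write_trace",
    "read_trace",
    "write_labels",
    "read_labels",
    "write_table",
    "read_table",
    "write_roi_matrix",
    "read_roi_matrix",
]

FLOAT_FMT = "%.10g"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_trace(trace: Trace, path: str | Path, params: SynthParams | None = None) -> Path:
    """Write a trace as 2-column TSV (time_s, amplitude) + YAML sidecar."""
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.times(), "amplitude": trace.samples})
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    meta = {
        "sampling_rate": float(trace.sampling_rate),
        "t0": float(trace.t0),
        "channel": trace.channel,
        "units": "a.u.",
    }
    if params is not None:
        meta["seed"] = int(params.seed)
        meta["params"] = {k: (None if isinstance(v, float) and np.isinf(v) else v)
                          for k, v in dataclasses.asdict(params).items()}
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    side = _sidecar_path(path)
    if side.exists():
        meta = yaml.safe_load(side.read_text())
        fs = float(meta["sampling_rate"])
        t0 = float(meta.get("t0", 0.0))
        channel = meta.get("channel", "")
    else:  # infer the rate from the time column
        t = df["time_s"].to_numpy(float)
        fs = 1.0 / float(np.median(np.diff(t)))
        t0 = float(t[0])
        channel = ""
    return Trace(df["amplitude"].to_numpy(float), fs, t0=t0, channel=channel)


def write_labels(labels: list[EventLabel], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": [e.time for e in labels],
            "peak_s": [e.peak_time for e in labels],
            "kind": [e.kind for e in labels],
            "shape_class": [e.shape_class for e in labels],
            "provenance": [e.provenance for e in labels],
            "amplitude": [e.amplitude for e in labels],
            "sweep": [-1 if e.sweep is None else e.sweep for e in labels],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


def read_labels(path: str | Path) -> list[EventLabel]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            EventLabel(
                time=float(row.time_s),
                kind=str(row.kind),
                peak_time=float(row.peak_s),
                shape_class=str(row.shape_class),
                provenance=str(row.provenance),
                amplitude=float(row.amplitude),
                sweep=None if int(row.sweep) < 0 else int(row.sweep),
            )
        )
    return out


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_roi_matrix(mat: ROIMatrix, path: str | Path) -> Path:
    """ROI matrix as TSV (time_s + one column per ROI) + sidecar."""
    path = Path(path)
    df = mat.data.reset_index()
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    meta: dict = {"sampling_rate": float(mat.sampling_rate)}
    if mat.roi_xy is not None:
        meta["roi_xy"] = {
            str(rid): [float(x), float(y)]
            for rid, (x, y) in mat.roi_xy.iterrows()
        }
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_roi_matrix(path: str | Path) -> ROIMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    time_col = df.columns[0]
    df = df.set_index(time_col)
    side = _sidecar_path(path)
    roi_xy = None
    if side.exists():
        meta = yaml.safe_load(side.read_text())
        fs = float(meta["sampling_rate"])
        if meta.get("roi_xy"):
            roi_xy = pd.DataFrame.from_dict(meta["roi_xy"], orient="index", columns=["x_um", "y_um"])
    else:
        t = df.index.to_numpy(float)
        fs = 1.0 / float(np.median(np.diff(t)))
    return ROIMatrix(data=df, sampling_rate=fs, roi_xy=roi_xy)


def save_prior(prior, path: str | Path) -> Path:
    """Persist a fitted ShapePrior/FeaturePrior as JSON for audit."""
    path = Path(path)
    d = dataclasses.asdict(prior)
    d["_type"] = type(prior).__name__
    payload = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in d.items()
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def load_prior(path: str | Path):
    from .classifier import FeaturePrior, ShapePrior

    payload = json.loads(Path(path).read_text())
    cls = {"ShapePrior": ShapePrior, "FeaturePrior": FeaturePrior}[payload.pop("_type")]
    fields = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for k, v in payload.items():
        if k not in fields:
            continue
        if isinstance(v, list):
            kwargs[k] = np.asarray(v)
        elif k == "feature_names":
            kwargs[k] = tuple(v)
        else:
            kwargs[k] = v
    if "feature_names" in kwargs and isinstance(kwargs["feature_names"], np.ndarray):
        kwargs["feature_names"] = tuple(kwargs["feature_names"].tolist())
    return cls(**kwargs)
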