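"""Readers and writers: raw traces, MAT-container adapters, result tables.

Raw traces are IEEE little-endian float binary (float32 or float64) or
single-column text.  The MAT adapter understands the layouts of the public
simulated benchmark (continuous trace plus spike times/classes) and paired
extra/intracellular recordings; variable names are configurable because the
public files do not standardize them.  Tables go through pandas as
tab-delimited text, metrics as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .detection import SpikeEvents
from .evaluation import GroundTruth, MetricsReport
from .features_clustering import ClusterLabels, FeatureMatrix
from .filtering import RawRecording

__all__ = [
    "read_raw",
    "write_raw",
    "read_mat_dataset",
    "events_table",
    "write_events_table",
    "write_truth_table",
    "read_truth_table",
    "write_metrics_json",
]

PathLike = Union[str, Path]

_DTYPES = {"float32": "<f4", "float64": "<f8"}


def read_raw(
    path: PathLike,
    rate_hz: float,
    format: str = "float_binary",
    dtype: str = "float32",
) -> RawRecording:
    """Load a continuous trace from float binary or single-column text."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "float_binary":
        samples = np.fromfile(path, dtype=np.dtype(_DTYPES[dtype]))
    elif format == "text":
        samples = np.loadtxt(path, ndmin=1)
    else:
        raise ValueError(f"unknown raw format {format!r}")
    if samples.size == 0:
        raise ValueError(f"no samples read from {path}")
    return RawRecording(samples=np.asarray(samples, dtype=np.float64), rate_hz=rate_hz)


def write_raw(
    path: PathLike,
    recording: RawRecording,
    format: str = "float_binary",
    dtype: str = "float32",
) -> None:
    path = Path(path)
    if format == "float_binary":
        recording.samples.astype(np.dtype(_DTYPES[dtype])).tofile(path)
    elif format == "text":
        np.savetxt(path, recording.samples, fmt="%.9g")
    else:
        raise ValueError(f"unknown raw format {format!r}")


_MAT_DEFAULTS = {
    "waveclus": {"trace": "data", "times": "spike_times", "classes": "spike_class", "rate": "sr"},
    "hc1": {"trace": "data", "times": "spike_times", "classes": "spike_class", "rate": "sr"},
}


def _load_mat(path: Path) -> dict:
    from scipy.io import loadmat

    try:
        raw = loadmat(path, squeeze_me=True)
        return {k: v for k, v in raw.items() if not k.startswith("__")}
    except NotImplementedError:
        # MAT v7.3 is HDF5
        import h5py

        out = {}
        with h5py.File(path, "r") as f:
            for k in f.keys():
                out[k] = np.asarray(f[k]).squeeze()
        return out


def read_mat_dataset(
    path: PathLike,
    layout: str = "waveclus",
    rate_hz: Optional[float] = None,
    var_names: Optional[dict] = None,
    times_unit: str = "samples",
) -> tuple[RawRecording, Optional[GroundTruth]]:
    """Load a MAT-container dataset: continuous trace plus, when present,
    spike times/classes as ground truth.

    Variable names default per layout (``trace``/``times``/``classes``/
    ``rate`` keys of ``var_names`` override).  ``times_unit`` says whether
    stored spike times are sample indices or seconds.  Ground-truth classes
    are remapped to contiguous 0-based units, preserving counts.
    """
    path = Path(path)
    if layout not in _MAT_DEFAULTS:
        raise ValueError(f"unknown layout {layout!r}; expected one of {sorted(_MAT_DEFAULTS)}")
    names = dict(_MAT_DEFAULTS[layout])
    if var_names:
        names.update(var_names)
    data = _load_mat(path)

    if names["trace"] not in data:
        raise KeyError(
            f"variable {names['trace']!r} (continuous trace) not found in {path.name}; "
            f"file has {sorted(data)}; expected names: {names}"
        )
    samples = np.asarray(data[names["trace"]], dtype=np.float64).ravel()

    if rate_hz is None:
        if names["rate"] in data:
            rate_hz = float(np.asarray(data[names["rate"]]).ravel()[0])
        else:
            raise ValueError(
                f"sampling rate not supplied and variable {names['rate']!r} absent from {path.name}"
            )
    recording = RawRecording(samples=samples, rate_hz=rate_hz)

    truth = None
    if names["times"] in data:
        times = np.asarray(data[names["times"]], dtype=np.float64).ravel()
        if times_unit == "samples":
            times = times / rate_hz
        elif times_unit != "seconds":
            raise ValueError(f"unknown times_unit {times_unit!r}")
        if names["classes"] in data:
            classes = np.asarray(data[names["classes"]]).ravel()
        else:
            classes = np.zeros(times.size)
        _, units = np.unique(classes, return_inverse=True)
        order = np.argsort(times, kind="stable")
        truth = GroundTruth(spike_times_s=times[order], unit_labels=units[order], kind="full")
    return recording, truth


def events_table(
    events: SpikeEvents,
    labels: Optional[ClusterLabels] = None,
    features: Optional[FeatureMatrix] = None,
) -> pd.DataFrame:
    """Tabulate events: 1-based peak samples (human-facing convention),
    times in seconds, signs, plus labels and feature scores when given."""
    df = pd.DataFrame(
        {
            "event_id": np.arange(events.n_events),
            "peak_sample": events.peak_indices + 1,
            "peak_time_s": events.peak_times_s,
            "peak_sign": events.peak_signs,
        }
    )
    if labels is not None:
        df["label"] = labels.labels
    if features is not None:
        for c in range(features.d):
            df[f"pc{c + 1}"] = features.scores[:, c]
    return df


def write_events_table(path: PathLike, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_truth_table(path: PathLike, truth: GroundTruth, overlap_flags=None) -> None:
    df = pd.DataFrame({"time_s": truth.spike_times_s, "unit": truth.unit_labels})
    if overlap_flags is not None:
        df["overlap_flag"] = np.asarray(overlap_flags).astype(int)
    df.to_csv(path, sep="\t", index=False)


def read_truth_table(path: PathLike, kind: str = "full") -> GroundTruth:
    df = pd.read_csv(path, sep="\t")
    return GroundTruth(
        spike_times_s=df["time_s"].to_numpy(),
        unit_labels=df["unit"].to_numpy(),
        kind=kind,
    )


def write_metrics_json(path: PathLike, metrics: MetricsReport) -> None:
    Path(path).write_text(json.dumps(metrics.to_dict(), indent=2, sort_keys=True) + "\n")
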