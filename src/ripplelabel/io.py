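"""Readers and writers for datasets, traces, checkpoints, and results.

Datasets travel as HDF5 containers (``signals`` matrix plus integer label
vectors, with the simulator configuration stored as a JSON attribute); raw
LFP comes in as two-column CSV (time, mV) or as a float array with a JSON
sidecar carrying the sampling rate; model checkpoints are numpy ``.npz``
archives of the parameter arrays.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .detect import LFPTrace
from .relabel import RelabelResult, SSLEncoder
from .simulate import LabeledDataset, SimConfig

__all__ = [
    "save_dataset",
    "load_dataset",
    "export_labels_csv",
    "save_embeddings",
    "load_embeddings",
    "read_lfp_csv",
    "save_relabel_csv",
    "save_checkpoint",
    "load_checkpoint",
]


def save_dataset(path: str | Path, dataset: LabeledDataset) -> None:
    """Write a labeled dataset to an HDF5 container (with JSON config attr)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=dataset.signals, compression="gzip")
        f.create_dataset("true_class", data=np.asarray(dataset.true_class, np.int64))
        f.create_dataset(
            "observed_label", data=np.asarray(dataset.observed_label, np.int64)
        )
        f.attrs["noise_proportion"] = dataset.noise_proportion
        f.attrs["config"] = json.dumps(dataclasses.asdict(dataset.config))


def load_dataset(path: str | Path) -> LabeledDataset:
    with h5py.File(path, "r") as f:
        cfg_dict = json.loads(f.attrs["config"])
        for key in ("duration_range", "delta_band", "gamma_band"):
            cfg_dict[key] = tuple(cfg_dict[key])
        return LabeledDataset(
            signals=f["signals"][:],
            true_class=f["true_class"][:],
            observed_label=f["observed_label"][:],
            noise_proportion=float(f.attrs["noise_proportion"]),
            config=SimConfig(**cfg_dict),
        )


def export_labels_csv(path: str | Path, dataset: LabeledDataset) -> None:
    """Write the label vectors (without signals) as a CSV table."""
    pd.DataFrame(
        {
            "row": np.arange(len(dataset)),
            "true_class": np.asarray(dataset.true_class),
            "observed_label": np.asarray(dataset.observed_label),
        }
    ).to_csv(path, index=False)


def save_embeddings(path: str | Path, embeddings: np.ndarray) -> None:
    """Store an embedding matrix alongside a saved dataset container."""
    with h5py.File(path, "a") as f:
        if "embeddings" in f:
            del f["embeddings"]
        f.create_dataset("embeddings", data=np.asarray(embeddings, np.float32))


def load_embeddings(path: str | Path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f["embeddings"][:]


def read_lfp_csv(path: str | Path, sampling_rate: float | None = None) -> LFPTrace:
    """Load a single-channel trace from (time, mV) or single-column CSV.

    With a time column the sampling rate is inferred from the median time
    step unless given explicitly.
    """
    frame = pd.read_csv(path)
    if frame.shape[1] >= 2:
        t = frame.iloc[:, 0].to_numpy(float)
        samples = frame.iloc[:, 1].to_numpy(float)
        if sampling_rate is None:
            dt = np.median(np.diff(t))
            if dt <= 0:
                raise ValueError("time column is not increasing")
            sampling_rate = 1.0 / dt
    else:
        if sampling_rate is None:
            raise ValueError("single-column CSV needs an explicit sampling_rate")
        samples = frame.iloc[:, 0].to_numpy(float)
    return LFPTrace(samples, float(sampling_rate))


def save_relabel_csv(
    path: str | Path, result: RelabelResult, observed: np.ndarray
) -> None:
    """Per-row relabeling audit table: observed label, group, intersection."""
    pd.DataFrame(
        {
            "row": np.arange(len(result.group)),
            "observed_label": np.asarray(observed),
            "group": result.group,
            "in_intersection": result.intersection_mask.astype(int),
        }
    ).to_csv(path, index=False)


def save_checkpoint(path: str | Path, model: SSLEncoder) -> None:
    np.savez(path, **model.state_dict())


def load_checkpoint(path: str | Path, model: SSLEncoder) -> SSLEncoder:
    """Load parameters saved by :func:`save_checkpoint` into ``model``."""
    with np.load(path) as archive:
        model.load_state_dict(dict(archive))
    return model
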