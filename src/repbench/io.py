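"""Readers and writers for the package's on-disk formats.

TrialTensor and FeatureMatrix live in HDF5; StimulusSet and RDMs in CSV;
NoiseModel and result bundles in JSON.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .data import FeatureMatrix, StimulusSet, TrialTensor

__all__ = [
    "save_feature_matrix", "load_feature_matrix",
    "save_trial_tensor", "load_trial_tensor",
    "save_rdm", "load_rdm",
    "save_json", "load_json",
]


def save_feature_matrix(rep: FeatureMatrix, path) -> None:
    path = str(path)
    if path.endswith(".csv"):
        cols = [f"f{j}" for j in range(rep.n_features)]
        pd.DataFrame(rep.values, columns=cols).to_csv(path, index=False)
        return
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("values", data=rep.values)
        ds.attrs["feature_kind"] = rep.feature_kind


def load_feature_matrix(path, stimuli: StimulusSet | None = None) -> FeatureMatrix:
    path = str(path)
    if path.endswith(".csv"):
        return FeatureMatrix(pd.read_csv(path).to_numpy(dtype=float),
                             stimuli=stimuli)
    with h5py.File(path, "r") as fh:
        vals = fh["values"][:]
        kind = fh["values"].attrs.get("feature_kind", "model")
    return FeatureMatrix(vals, feature_kind=str(kind), stimuli=stimuli)


def save_trial_tensor(tensor: TrialTensor, path) -> None:
    with h5py.File(str(path), "w") as fh:
        fh.create_dataset("counts", data=tensor.counts)
        fh.create_dataset("blank_rate", data=tensor.blank_rate)
        fh.attrs["window"] = tensor.window


def load_trial_tensor(path) -> TrialTensor:
    with h5py.File(str(path), "r") as fh:
        return TrialTensor(counts=fh["counts"][:],
                           blank_rate=fh["blank_rate"][:],
                           window=tuple(fh.attrs["window"]))


def save_rdm(rdm: np.ndarray, objects: list, path) -> None:
    pd.DataFrame(rdm, index=objects, columns=objects).to_csv(path)


def load_rdm(path) -> tuple[np.ndarray, list]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), df.index.tolist()


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2)


def load_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
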