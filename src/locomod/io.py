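"""HDF5/CSV containers for tensors, models, and recordings.

Layouts
-------
Tensor container (HDF5): datasets ``X`` (S x T x K), ``subject_id``,
``speed``, ``mode``, ``speed_bin_index`` (per task), ``channel_labels``;
attributes ``nonneg``, plus any ``seed`` / ``config`` echo passed by the
caller.  Ground-truth containers add ``weights``/``spatial``/``temporal``/
``task`` and the profile labels.  Model containers mirror the factor
datasets and store the fit diagnostics as attributes with the objective
history as a dataset.

Recordings travel as CSV (``time_s``, one column per channel, ``grf_z``)
with a JSON metadata sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .datatypes import CPModel, DataTensor, FitDiagnostics, GroundTruthModel, TaskDescriptor
from .synthetic import MotionRecording

__all__ = [
    "save_tensor", "load_tensor",
    "save_model", "load_model",
    "save_ground_truth", "load_ground_truth",
    "save_recording", "load_recording",
]

_STR = h5py.string_dtype("utf-8")


def _write_descriptors(g: h5py.Group, descriptors) -> None:
    g.create_dataset("subject_id", data=np.array([d.subject_id for d in descriptors]))
    g.create_dataset("speed", data=np.array([d.speed for d in descriptors]))
    g.create_dataset("mode", data=np.array([d.mode for d in descriptors], dtype=_STR))
    g.create_dataset("speed_bin_index", data=np.array(
        [-1 if d.speed_bin_index is None else d.speed_bin_index
         for d in descriptors]))


def _read_descriptors(g: h5py.Group):
    subj = g["subject_id"][:]
    speed = g["speed"][:]
    mode = [m.decode() if isinstance(m, bytes) else str(m) for m in g["mode"][:]]
    bins = g["speed_bin_index"][:]
    return [TaskDescriptor(subject_id=int(s), speed=float(v), mode=m,
                           speed_bin_index=None if b < 0 else int(b))
            for s, v, m, b in zip(subj, speed, mode, bins)]


def save_tensor(path, tensor: DataTensor, seed: Optional[int] = None,
                config_json: Optional[str] = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=tensor.X)
        f.create_dataset("channel_labels",
                         data=np.array(list(tensor.channel_labels), dtype=_STR))
        _write_descriptors(f.create_group("tasks"), tensor.task_descriptors)
        f.attrs["nonneg"] = tensor.nonneg
        if seed is not None:
            f.attrs["seed"] = seed
        if config_json is not None:
            f.attrs["config"] = config_json


def load_tensor(path) -> DataTensor:
    with h5py.File(path, "r") as f:
        labels = [s.decode() if isinstance(s, bytes) else str(s)
                  for s in f["channel_labels"][:]]
        return DataTensor(X=f["X"][:], channel_labels=labels,
                          task_descriptors=_read_descriptors(f["tasks"]),
                          nonneg=bool(f.attrs.get("nonneg", False)))


def _write_factors(f, model: CPModel) -> None:
    f.create_dataset("weights", data=model.weights)
    f.create_dataset("spatial", data=model.spatial)
    f.create_dataset("temporal", data=model.temporal)
    f.create_dataset("task", data=model.task)
    f.attrs["nonneg"] = model.nonneg
    if model.sign_flips is not None:
        f.create_dataset("sign_flips", data=model.sign_flips)


def _read_factors(f) -> CPModel:
    return CPModel(weights=f["weights"][:], spatial=f["spatial"][:],
                   temporal=f["temporal"][:], task=f["task"][:],
                   nonneg=bool(f.attrs.get("nonneg", False)),
                   sign_flips=f["sign_flips"][:] if "sign_flips" in f else None)


def save_model(path, model: CPModel, diagnostics: Optional[FitDiagnostics] = None,
               config_json: Optional[str] = None) -> None:
    with h5py.File(path, "w") as f:
        _write_factors(f, model)
        if diagnostics is not None:
            d = f.create_group("diagnostics")
            for k in ("objective", "rel_fitting_error", "vaf", "n_iter",
                      "converged", "n_restarts", "best_restart_seed"):
                d.attrs[k] = getattr(diagnostics, k)
            d.create_dataset("objective_history",
                             data=np.asarray(diagnostics.objective_history))
        if config_json is not None:
            f.attrs["config"] = config_json


def load_model(path):
    with h5py.File(path, "r") as f:
        model = _read_factors(f)
        diag = None
        if "diagnostics" in f:
            d = f["diagnostics"]
            diag = FitDiagnostics(
                objective=float(d.attrs["objective"]),
                rel_fitting_error=float(d.attrs["rel_fitting_error"]),
                vaf=float(d.attrs["vaf"]), n_iter=int(d.attrs["n_iter"]),
                converged=bool(d.attrs["converged"]),
                n_restarts=int(d.attrs["n_restarts"]),
                best_restart_seed=int(d.attrs["best_restart_seed"]),
                objective_history=d["objective_history"][:])
    return model, diag


def save_ground_truth(path, truth: GroundTruthModel) -> None:
    with h5py.File(path, "w") as f:
        _write_factors(f, truth.model)
        _write_descriptors(f.create_group("tasks"), truth.task_descriptors)
        f.create_dataset("profiles",
                         data=np.array(list(truth.profiles), dtype=_STR))
        f.attrs["noise_sd"] = truth.noise_sd
        if truth.seed is not None:
            f.attrs["seed"] = truth.seed


def load_ground_truth(path) -> GroundTruthModel:
    with h5py.File(path, "r") as f:
        model = _read_factors(f)
        descriptors = _read_descriptors(f["tasks"])
        profiles = [p.decode() if isinstance(p, bytes) else str(p)
                    for p in f["profiles"][:]]
        return GroundTruthModel(model=model, task_descriptors=descriptors,
                                profiles=profiles,
                                noise_sd=float(f.attrs.get("noise_sd", 0.0)),
                                seed=int(f.attrs["seed"]) if "seed" in f.attrs else None)


def save_recording(csv_path, recording: MotionRecording,
                   meta_path=None) -> None:
    csv_path = Path(csv_path)
    n = recording.signals.shape[1]
    df = pd.DataFrame({"time_s": np.arange(n) / recording.fs})
    labels = recording.channel_labels or [
        f"ch{i}" for i in range(recording.signals.shape[0])]
    for i, lab in enumerate(labels):
        df[lab] = recording.signals[i]
    df["grf_z"] = recording.grf_z
    df.to_csv(csv_path, index=False)
    meta = {"fs": recording.fs, "channel_labels": list(labels)}
    if recording.true_contacts is not None:
        meta["true_contacts"] = [int(i) for i in recording.true_contacts]
    if recording.true_toe_offs is not None:
        meta["true_toe_offs"] = [int(i) for i in recording.true_toe_offs]
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".json")
    meta_path.write_text(json.dumps(meta, indent=2))


def load_recording(csv_path, meta_path=None) -> MotionRecording:
    csv_path = Path(csv_path)
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".json")
    meta = json.loads(meta_path.read_text())
    df = pd.read_csv(csv_path)
    labels = meta["channel_labels"]
    signals = np.vstack([df[lab].to_numpy() for lab in labels])
    return MotionRecording(
        signals=signals, grf_z=df["grf_z"].to_numpy(), fs=float(meta["fs"]),
        channel_labels=labels,
        true_contacts=np.array(meta["true_contacts"], dtype=int)
        if "true_contacts" in meta else None,
        true_toe_offs=np.array(meta["true_toe_offs"], dtype=int)
        if "true_toe_offs" in meta else None)
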