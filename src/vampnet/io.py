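"""Trajectory, checkpoint and score-trace I/O.

Trajectories are stored as (n_frames, dim) float arrays, either in an
HDF5 dataset (with the simulation parameters as attributes) or as
headerless delimited text.  Trained models are checkpointed to HDF5 with
the lobe weights, the architecture, the training lag and the seed, which
is everything needed to rebuild the transformation.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import h5py
import numpy as np

from .network import LobeSpec, TrainedVAMPnet, build_lobe

__all__ = [
    "save_trajectory",
    "load_trajectory",
    "save_checkpoint",
    "load_checkpoint",
    "write_score_trace",
    "write_scores_json",
]


def save_trajectory(
    path: str | Path, traj: np.ndarray, metadata: dict | None = None
) -> None:
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("trajectory", data=np.asarray(traj, dtype=np.float64))
        for key, val in (metadata or {}).items():
            dset.attrs[key] = val


def load_trajectory(path: str | Path, dataset: str = "trajectory") -> np.ndarray:
    """Load a trajectory from HDF5 (by extension) or headerless text."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5", ".hdf"):
        with h5py.File(path, "r") as f:
            arr = np.asarray(f[dataset][...], dtype=np.float64)
    else:
        arr = np.loadtxt(path, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def save_checkpoint(path: str | Path, model: TrainedVAMPnet) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["widths"] = model.spec.widths
        f.attrs["dropout"] = model.spec.dropout
        f.attrs["l2_hidden"] = model.spec.l2_hidden
        f.attrs["l2_output"] = model.spec.l2_output
        f.attrs["lag"] = model.lag
        f.attrs["k"] = model.k
        f.attrs["seed"] = model.seed
        f.attrs["best_epoch"] = model.best_epoch
        f.attrs["best_val_score"] = model.best_val_score
        g = f.create_group("parameters")
        for i, (W, b) in enumerate(zip(model.lobe.weights, model.lobe.biases)):
            g.create_dataset(f"W{i}", data=W)
            g.create_dataset(f"b{i}", data=b)
        f.create_dataset("train_scores", data=np.asarray(model.train_scores))
        f.create_dataset("val_scores", data=np.asarray(model.val_scores))
        f.create_dataset("learning_rates", data=np.asarray(model.learning_rates))


def load_checkpoint(path: str | Path) -> TrainedVAMPnet:
    with h5py.File(path, "r") as f:
        widths = [int(w) for w in f.attrs["widths"]]
        spec = LobeSpec(
            n_in=widths[0],
            n_out=widths[-1],
            widths=widths,
            dropout=[float(p) for p in f.attrs["dropout"]],
            l2_hidden=float(f.attrs["l2_hidden"]),
            l2_output=float(f.attrs["l2_output"]),
        )
        lobe = build_lobe(spec, seed=0)
        g = f["parameters"]
        for i in range(spec.depth):
            lobe.weights[i][...] = g[f"W{i}"][...]
            lobe.biases[i][...] = g[f"b{i}"][...]
        return TrainedVAMPnet(
            lobe=lobe,
            spec=spec,
            lag=int(f.attrs["lag"]),
            k=int(f.attrs["k"]),
            train_scores=list(f["train_scores"][...]),
            val_scores=list(f["val_scores"][...]),
            learning_rates=list(f["learning_rates"][...]),
            best_epoch=int(f.attrs["best_epoch"]),
            best_val_score=float(f.attrs["best_val_score"]),
            seed=int(f.attrs["seed"]),
        )


def write_score_trace(path: str | Path, model: TrainedVAMPnet) -> None:
    """Per-epoch CSV trace: epoch, train_score, val_score, lr."""
    with open(path, "w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(["epoch", "train_score", "val_score", "lr"])
        for i, (tr, va, lr) in enumerate(
            zip(model.train_scores, model.val_scores, model.learning_rates)
        ):
            writer.writerow([i, f"{tr:.10g}", f"{va:.10g}", f"{lr:.10g}"])


def write_scores_json(path: str | Path, reports) -> None:
    """Write ScoreReport records as a JSON list."""
    with open(path, "w") as f:
        json.dump([json.loads(r.to_json()) for r in reports], f, indent=1)
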