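"""Sequence preprocessing and dataset I/O.

Preprocessing follows the standard recipe for paired skeleton/IMU action
data: every sequence is linearly resampled onto a fixed 50-step grid, and
skeletons are expressed in the reference frame of their first frame — the
reference joint's first-frame position becomes the origin and the RMS
distance of the first-frame joints to that joint becomes the unit of
length.  IMU channels are z-scored with statistics taken from the training
split only.

Datasets are stored as one HDF5 container per split (arrays ``skeleton``
N×C×T×V, ``imu`` N×T×S, ``labels`` N, ``subjects`` N) with a JSON sidecar
holding the generator configuration; IMU sequences can also be exported as
per-sequence CSV (rows = time steps, columns = channels).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .synthetic import GeneratorConfig, LabeledSample

__all__ = [
    "resample_sequence",
    "normalize_skeleton",
    "zscore_imu",
    "write_dataset",
    "read_dataset",
    "export_imu_csv",
]


def resample_sequence(x: np.ndarray, target_len: int, axis: int = 0) -> np.ndarray:
    """Linearly resample ``x`` along ``axis`` onto a uniform grid of
    ``target_len`` points spanning [0, T_in - 1].  Endpoints are preserved
    exactly and the same interpolation is applied to every other axis."""
    x = np.asarray(x, dtype=np.float64)
    t_in = x.shape[axis]
    if t_in < 2:
        raise ValueError("resampling requires an input length of at least 2")
    if target_len < 1:
        raise ValueError("target_len must be positive")
    grid = np.linspace(0.0, t_in - 1.0, target_len)
    lo = np.floor(grid).astype(int)
    hi = np.minimum(lo + 1, t_in - 1)
    w = (grid - lo).reshape((-1,) + (1,) * (x.ndim - 1))
    xm = np.moveaxis(x, axis, 0)
    out = (1.0 - w) * xm[lo] + w * xm[hi]
    return np.moveaxis(out, 0, axis)


def normalize_skeleton(skeleton: np.ndarray, reference_joint: int = 0) -> np.ndarray:
    """Express a (C, T, V) skeleton in its first-frame reference frame.

    Subtracts the first frame's reference-joint coordinates from every
    frame and joint, then divides by the first-frame scale: the RMS
    distance of the first-frame joints to the reference joint.
    """
    skeleton = np.asarray(skeleton, dtype=np.float64)
    if skeleton.ndim != 3:
        raise ValueError("skeleton must have shape (C, T, V)")
    C, T, V = skeleton.shape
    if not 0 <= reference_joint < V:
        raise ValueError(f"reference_joint must be in [0, {V})")
    origin = skeleton[:, 0, reference_joint]  # (C,)
    centered = skeleton - origin[:, None, None]
    first = centered[:, 0, :]  # (C, V)
    scale = np.sqrt(np.mean(np.sum(first**2, axis=0)))
    if scale <= 1e-12:
        raise ValueError("degenerate pose: all first-frame joints coincide "
                         "with the reference joint")
    return centered / scale


def zscore_imu(
    train: Sequence[np.ndarray], others: Sequence[Sequence[np.ndarray]] = ()
) -> tuple[list[np.ndarray], list[list[np.ndarray]]]:
    """Per-channel z-scoring using training-split statistics.

    Returns the standardised training sequences and, standardised with the
    same statistics, each additional collection in ``others``.
    """
    stacked = np.concatenate([np.asarray(x) for x in train], axis=0)
    mean = stacked.mean(axis=0)
    sd = stacked.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    tr = [(np.asarray(x) - mean) / sd for x in train]
    rest = [[(np.asarray(x) - mean) / sd for x in grp] for grp in others]
    return tr, rest


def _stack(samples: Sequence[LabeledSample]):
    skeleton = np.stack([s.skeleton for s in samples]) if samples else np.zeros((0,))
    imu = np.stack([s.imu for s in samples]) if samples else np.zeros((0,))
    labels = np.array([s.label for s in samples], dtype=np.int64)
    subjects = np.array([s.subject for s in samples], dtype=np.int64)
    return skeleton, imu, labels, subjects


def write_dataset(
    samples: Sequence[LabeledSample],
    path: str | Path,
    config: GeneratorConfig | None = None,
) -> None:
    """Write samples to an HDF5 container plus a JSON metadata sidecar."""
    path = Path(path)
    skeleton, imu, labels, subjects = _stack(list(samples))
    with h5py.File(path, "w") as f:
        f.create_dataset("skeleton", data=skeleton)
        f.create_dataset("imu", data=imu)
        f.create_dataset("labels", data=labels)
        f.create_dataset("subjects", data=subjects)
    meta = {"n_samples": len(samples), "format_version": 1}
    if config is not None:
        meta["generator_config"] = dataclasses.asdict(config)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_dataset(path: str | Path) -> list[LabeledSample]:
    """Read a dataset container; round-trips :func:`write_dataset` bit-exactly."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        for key in ("skeleton", "imu", "labels", "subjects"):
            if key not in f:
                raise ValueError(f"dataset file {path} is missing array '{key}'")
        skeleton = f["skeleton"][...]
        imu = f["imu"][...]
        labels = f["labels"][...]
        subjects = f["subjects"][...]
    n = len(labels)
    if n == 0:
        return []
    if skeleton.shape[0] != n or imu.shape[0] != n or subjects.shape[0] != n:
        raise ValueError("array leading dimensions disagree on sample count")
    if skeleton.ndim != 4 or imu.ndim != 3:
        raise ValueError("expected skeleton N×C×T×V and imu N×T×S arrays")
    return [
        LabeledSample(skeleton=skeleton[i], imu=imu[i],
                      label=int(labels[i]), subject=int(subjects[i]))
        for i in range(n)
    ]


def export_imu_csv(sample: LabeledSample, path: str | Path) -> None:
    """Write one IMU sequence as CSV: rows = time steps, columns = channels."""
    s = np.asarray(sample.imu)
    df = pd.DataFrame(s, columns=[f"ch{j}" for j in range(s.shape[1])])
    df.index.name = "frame"
    df.to_csv(path)
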