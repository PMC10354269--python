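"""Stochastic, modality-specific augmentation pipelines.

These create the randomly perturbed "views" that the contrastive
objectives compare.  Skeleton views use geometric transforms (jitter,
scale, rotation, shear, temporal crop-and-resize); IMU views use signal
transforms (jitter, scale, per-triple 3-D rotation, segment permutation,
channel shuffle).  Every transform is shape-preserving and exactly
reproducible given the random generator passed in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .preprocess import resample_sequence
from .synthetic import LabeledSample

__all__ = [
    "AugmentationSpec",
    "SKELETON_AUGMENTATIONS",
    "IMU_AUGMENTATIONS",
    "default_skeleton_pipeline",
    "default_imu_pipeline",
    "multimodal_skeleton_pipeline",
    "multimodal_imu_pipeline",
    "augment_skeleton",
    "augment_imu",
    "make_view_pair",
]

SKELETON_AUGMENTATIONS = frozenset({"jitter", "scale", "rotate", "shear", "crop_resize"})
IMU_AUGMENTATIONS = frozenset({"jitter", "scale", "rotate", "permute_segments", "channel_shuffle"})

_DEFAULT_PARAMS = {
    "jitter": {"jitter_sd": 0.05},
    "scale": {"scale_min": 0.8, "scale_max": 1.2},
    "rotate": {"angle_range_deg": 30.0},
    "shear": {"shear_range": 0.2},
    "crop_resize": {"crop_min_fraction": 0.6},
    "permute_segments": {"num_segments": 4},
    "channel_shuffle": {},
}


@dataclass(frozen=True)
class AugmentationSpec:
    """One pipeline stage: a named transform, its parameters, and the
    probability with which it is applied."""

    name: str
    probability: float = 0.5
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in _DEFAULT_PARAMS:
            raise ValueError(f"unknown augmentation {self.name!r}")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")
        merged = dict(_DEFAULT_PARAMS[self.name])
        merged.update(self.params)
        object.__setattr__(self, "params", merged)
        if self.name == "jitter" and merged["jitter_sd"] < 0:
            raise ValueError("jitter_sd must be non-negative")
        if self.name == "scale" and not 0 < merged["scale_min"] <= merged["scale_max"]:
            raise ValueError("scale range must satisfy 0 < scale_min <= scale_max")
        if self.name == "crop_resize" and not 0 < merged["crop_min_fraction"] <= 1.0:
            raise ValueError("crop_min_fraction must be in (0, 1]")
        if self.name == "permute_segments" and int(merged["num_segments"]) < 1:
            raise ValueError("num_segments must be >= 1")


def default_skeleton_pipeline(probability: float = 0.5) -> list[AugmentationSpec]:
    return [AugmentationSpec(n, probability)
            for n in ("jitter", "scale", "rotate", "shear", "crop_resize")]


def default_imu_pipeline(probability: float = 0.5, with_rotation: bool = True) -> list[AugmentationSpec]:
    names = ["jitter", "scale"]
    if with_rotation:
        names.append("rotate")
    names += ["permute_segments", "channel_shuffle"]
    return [AugmentationSpec(n, probability) for n in names]


def multimodal_skeleton_pipeline(probability: float = 0.3) -> list[AugmentationSpec]:
    """Gentler skeleton pipeline for cross-modal pretraining.

    When the two views come from different modalities, the modality gap is
    itself the dominant view difference; augmentation applied to one branch
    is nuisance variance the other branch cannot mirror, and with the
    invariance term summed over embedding dimensions it directly lowers the
    variance equilibrium.  Cross-modal pretraining therefore defaults to
    lower probabilities and magnitudes than the unimodal two-view setting.
    """
    return [
        AugmentationSpec("jitter", probability, {"jitter_sd": 0.02}),
        AugmentationSpec("scale", probability, {"scale_min": 0.9, "scale_max": 1.1}),
        AugmentationSpec("rotate", probability, {"angle_range_deg": 10.0}),
        AugmentationSpec("shear", probability, {"shear_range": 0.1}),
        AugmentationSpec("crop_resize", probability, {"crop_min_fraction": 0.8}),
    ]


def multimodal_imu_pipeline(probability: float = 0.3, with_rotation: bool = True) -> list[AugmentationSpec]:
    """Gentler IMU pipeline for cross-modal pretraining (see
    :func:`multimodal_skeleton_pipeline`)."""
    pipe = [
        AugmentationSpec("jitter", probability, {"jitter_sd": 0.02}),
        AugmentationSpec("scale", probability, {"scale_min": 0.9, "scale_max": 1.1}),
    ]
    if with_rotation:
        pipe.append(AugmentationSpec("rotate", probability, {"angle_range_deg": 10.0}))
    pipe += [AugmentationSpec("permute_segments", probability),
             AugmentationSpec("channel_shuffle", probability)]
    return pipe


def _rotation_matrix(dim: int, angle_deg: float, rng: np.random.Generator) -> np.ndarray:
    angle = math.radians(rng.uniform(-angle_deg, angle_deg))
    if dim == 2:
        c, s = math.cos(angle), math.sin(angle)
        return np.array([[c, -s], [s, c]])
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def augment_skeleton(
    x: np.ndarray,
    pipeline: list[AugmentationSpec],
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply a skeleton pipeline to a (C, T, V) tensor, stage by stage."""
    bad = [s.name for s in pipeline if s.name not in SKELETON_AUGMENTATIONS]
    if bad:
        raise ValueError(f"augmentations {bad} are not valid for skeletons")
    out = np.asarray(x, dtype=np.float64).copy()
    C, T, V = out.shape
    for spec in pipeline:
        if rng.random() >= spec.probability:
            continue
        p = spec.params
        if spec.name == "jitter":
            out = out + rng.normal(0.0, p["jitter_sd"], size=out.shape)
        elif spec.name == "scale":
            out = out * rng.uniform(p["scale_min"], p["scale_max"])
        elif spec.name == "rotate":
            R = _rotation_matrix(C, p["angle_range_deg"], rng)
            out = np.einsum("cd,dtv->ctv", R, out)
        elif spec.name == "shear":
            M = np.eye(C)
            off = ~np.eye(C, dtype=bool)
            M[off] = rng.uniform(-p["shear_range"], p["shear_range"], size=off.sum())
            out = np.einsum("cd,dtv->ctv", M, out)
        elif spec.name == "crop_resize":
            frac = rng.uniform(p["crop_min_fraction"], 1.0)
            length = max(2, int(round(frac * T)))
            start = int(rng.integers(0, T - length + 1))
            out = resample_sequence(out[:, start : start + length, :], T, axis=1)
    return out


def augment_imu(
    x: np.ndarray,
    pipeline: list[AugmentationSpec],
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply an IMU pipeline to a (T, S) matrix, stage by stage."""
    bad = [s.name for s in pipeline if s.name not in IMU_AUGMENTATIONS]
    if bad:
        raise ValueError(f"augmentations {bad} are not valid for IMU signals")
    out = np.asarray(x, dtype=np.float64).copy()
    T, S = out.shape
    for spec in pipeline:
        if rng.random() >= spec.probability:
            continue
        p = spec.params
        if spec.name == "jitter":
            out = out + rng.normal(0.0, p["jitter_sd"], size=out.shape)
        elif spec.name == "scale":
            out = out * rng.uniform(p["scale_min"], p["scale_max"])
        elif spec.name == "rotate":
            if S % 3 != 0:
                raise ValueError(
                    f"IMU rotation needs channel count divisible by 3, got {S}")
            for g in range(S // 3):
                R = _rotation_matrix(3, p["angle_range_deg"], rng)
                out[:, 3 * g : 3 * g + 3] = out[:, 3 * g : 3 * g + 3] @ R.T
        elif spec.name == "permute_segments":
            k = int(p["num_segments"])
            blocks = np.array_split(np.arange(T), k)
            order = rng.permutation(len(blocks))
            out = out[np.concatenate([blocks[i] for i in order])]
        elif spec.name == "channel_shuffle":
            out = out[:, rng.permutation(S)]
    return out


def make_view_pair(
    sample: LabeledSample,
    skeleton_pipeline: list[AugmentationSpec] | None,
    imu_pipeline: list[AugmentationSpec] | None,
    rng: np.random.Generator,
    mode: str = "multimodal",
) -> tuple[np.ndarray, np.ndarray]:
    """Produce the two views the contrastive objectives consume.

    ``unimodal_skeleton`` / ``unimodal_imu`` return two independently
    augmented views of the one modality; ``multimodal`` returns one
    augmented view per modality (skeleton view first).
    """
    if skeleton_pipeline is None and imu_pipeline is None:
        raise ValueError("at least one augmentation pipeline must be supplied")
    if mode == "unimodal_skeleton":
        pipe = skeleton_pipeline or []
        return (augment_skeleton(sample.skeleton, pipe, rng),
                augment_skeleton(sample.skeleton, pipe, rng))
    if mode == "unimodal_imu":
        pipe = imu_pipeline or []
        return (augment_imu(sample.imu, pipe, rng),
                augment_imu(sample.imu, pipe, rng))
    if mode == "multimodal":
        return (augment_skeleton(sample.skeleton, skeleton_pipeline or [], rng),
                augment_imu(sample.imu, imu_pipeline or [], rng))
    raise ValueError(f"unknown view mode {mode!r}")
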