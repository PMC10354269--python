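"""Named configuration profiles.

The benchmark-scale profiles carry the published pretraining settings for
the two reference benchmarks (learning rate, epochs, batch size per
modality regime); ``small_synthetic`` is the desk-scale profile used by
the test-suite and the reproduction script: batch 32, 50 epochs,
32-dimensional embeddings and narrow encoders so a full pipeline runs in
minutes on one CPU core.
"""

from __future__ import annotations

from .encoders import IMUEncoderConfig, ProjectorConfig, SkeletonEncoderConfig
from .pretrain import SMALL_IMU_CONFIG, SMALL_PROJECTOR_CONFIG, SMALL_SKELETON_CONFIG

__all__ = ["PRESETS", "get_preset"]

_FULL_ENCODERS = {
    "imu_config": IMUEncoderConfig(),
    "skeleton_config": SkeletonEncoderConfig(),
    "projector_config": ProjectorConfig(),
}

_SMALL_ENCODERS = {
    "imu_config": SMALL_IMU_CONFIG,
    "skeleton_config": SMALL_SKELETON_CONFIG,
    "projector_config": SMALL_PROJECTOR_CONFIG,
}

PRESETS: dict[str, dict] = {
    "utd_unimodal": {**_FULL_ENCODERS, "learning_rate": 1e-2, "epochs": 100, "batch_size": 128},
    "utd_multimodal": {**_FULL_ENCODERS, "learning_rate": 1e-3, "epochs": 200, "batch_size": 256},
    "mmact_unimodal": {**_FULL_ENCODERS, "learning_rate": 1e-3, "epochs": 100, "batch_size": 96},
    "mmact_multimodal": {**_FULL_ENCODERS, "learning_rate": 1e-4, "epochs": 200, "batch_size": 128},
    "small_synthetic": {**_SMALL_ENCODERS, "learning_rate": 1e-2, "epochs": 50, "batch_size": 32},
}


def get_preset(name: str) -> dict:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return dict(PRESETS[name])
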