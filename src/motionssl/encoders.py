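"""Modality-specific feature encoders and projection heads.

* :class:`IMUEncoder` — three temporal 1-D convolution blocks (channels
  [32, 64, 128], kernel 3, batch norm + ReLU) followed by a fixed
  sinusoidal positional signal, a stack of pre-norm transformer blocks
  (2 heads by default) and global average pooling over time.

* :class:`SkeletonEncoder` — a two-stream co-occurrence style network.
  The *joint* stream sees raw coordinates (C, T, V); the *motion* stream
  sees their temporal differences (edge-padded to length T).  Each stream
  applies six 2-D convolution blocks with channels [64, 32, 32, 64, 128,
  256]; after the third block the joint axis is transposed into the
  channel dimension so early blocks encode point-level information of each
  joint independently while late blocks aggregate globally across joints.
  The exact transpose placement and strides are an interpretation of the
  published block diagram (the figure is not fully specified); they are
  fixed here and regression-tested through parameter counts.  Streams are
  fused by channel concatenation and a linear map to the hidden width.

* :class:`Projector` — a small MLP (batch norm + ReLU between layers,
  final layer linear) mapping hidden features to the embedding space where
  the contrastive losses act.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .autograd import Tensor, concatenate

__all__ = [
    "IMUEncoderConfig",
    "SkeletonEncoderConfig",
    "ProjectorConfig",
    "IMUEncoder",
    "SkeletonEncoder",
    "Projector",
]


@dataclass(frozen=True)
class IMUEncoderConfig:
    conv_channels: tuple[int, ...] = (32, 64, 128)
    kernel_size: int = 3
    attention_heads: int = 2
    attention_blocks: int = 2
    model_dim: int = 128

    def validate(self) -> None:
        if not self.conv_channels:
            raise ValueError("conv_channels must be nonempty")
        if self.conv_channels[-1] != self.model_dim:
            raise ValueError("last conv channel must equal model_dim")
        if self.model_dim % self.attention_heads != 0:
            raise ValueError("model_dim must be divisible by attention_heads")

    @property
    def hidden_dim(self) -> int:
        return self.model_dim


@dataclass(frozen=True)
class SkeletonEncoderConfig:
    conv_channels: tuple[int, ...] = (64, 32, 32, 64, 128, 256)
    hidden_dim: int = 256

    def validate(self) -> None:
        if len(self.conv_channels) != 6:
            raise ValueError("skeleton encoder requires exactly 6 conv blocks")


@dataclass(frozen=True)
class ProjectorConfig:
    layer_dims: tuple[int, ...] = (256, 128)

    def validate(self) -> None:
        if not self.layer_dims:
            raise ValueError("layer_dims must be nonempty")

    @property
    def embedding_dim(self) -> int:
        return self.layer_dims[-1]


def _lift(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class IMUEncoder(nn.Module):
    """Maps an (n, T, S) inertial batch to (n, model_dim) hidden features."""

    def __init__(self, in_channels: int, config: IMUEncoderConfig, rng: np.random.Generator):
        super().__init__()
        config.validate()
        self.config = config
        self.in_channels = in_channels
        blocks = []
        prev = in_channels
        for ch in config.conv_channels:
            blocks += [nn.Conv1d(prev, ch, config.kernel_size, rng),
                       nn.BatchNorm(ch), nn.ReLU()]
            prev = ch
        self.conv = nn.Sequential(*blocks)
        self.blocks = [nn.TransformerBlock(config.model_dim, config.attention_heads, rng)
                       for _ in range(config.attention_blocks)]

    @property
    def hidden_dim(self) -> int:
        return self.config.model_dim

    def forward(self, x) -> Tensor:
        x = _lift(x)
        if x.ndim != 3:
            raise ValueError("IMU batch must have shape (n, T, S)")
        n, T, S = x.shape
        if S != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {S}")
        if T < self.config.kernel_size:
            raise ValueError("sequence shorter than the convolution kernel")
        h = self.conv(x.transpose(0, 2, 1))  # (n, model_dim, T)
        h = h.transpose(0, 2, 1)  # (n, T, model_dim)
        h = h + Tensor(nn.sinusoidal_positions(T, self.config.model_dim))
        for block in self.blocks:
            h = block(h)
        return h.mean(axis=1)  # global average pooling over time


def motion_stream(x: np.ndarray) -> np.ndarray:
    """Temporal difference of an (n, C, T, V) batch, edge-padded to length T."""
    d = np.diff(x, axis=2)
    return np.concatenate([d, d[:, :, -1:, :]], axis=2)


class _SkeletonStream(nn.Module):
    """Six conv blocks with a mid-network transpose of joints into channels."""

    def __init__(self, coord_dim: int, joints: int, channels: tuple[int, ...],
                 rng: np.random.Generator):
        super().__init__()
        c1, c2, c3, c4, c5, c6 = channels
        self.early = nn.Sequential(
            nn.Conv2d(coord_dim, c1, (3, 3), rng), nn.BatchNorm(c1), nn.ReLU(),
            nn.Conv2d(c1, c2, (3, 3), rng), nn.BatchNorm(c2), nn.ReLU(),
            nn.Conv2d(c2, c3, (3, 3), rng), nn.BatchNorm(c3), nn.ReLU(),
        )
        # After the transpose the channel axis is the joint axis; spatial
        # axes are (time, early-channels).
        self.late = nn.Sequential(
            nn.Conv2d(joints, c4, (3, 3), rng, stride=(2, 2)), nn.BatchNorm(c4), nn.ReLU(),
            nn.Conv2d(c4, c5, (3, 3), rng, stride=(2, 2)), nn.BatchNorm(c5), nn.ReLU(),
            nn.Conv2d(c5, c6, (3, 3), rng, stride=(2, 2)), nn.BatchNorm(c6), nn.ReLU(),
        )

    def forward(self, x: Tensor) -> Tensor:
        h = self.early(x)  # (n, c3, T, V): point-level, per-joint
        h = h.transpose(0, 3, 2, 1)  # (n, V, T, c3): joints become channels
        h = self.late(h)  # (n, c6, T', W'): global aggregation across joints
        return h.mean(axis=(2, 3))  # (n, c6)


class SkeletonEncoder(nn.Module):
    """Maps an (n, C, T, V) skeleton batch to (n, hidden_dim) features."""

    def __init__(self, coord_dim: int, joints: int, config: SkeletonEncoderConfig,
                 rng: np.random.Generator):
        super().__init__()
        config.validate()
        self.config = config
        self.coord_dim = coord_dim
        self.joints = joints
        self.joint_stream = _SkeletonStream(coord_dim, joints, config.conv_channels, rng)
        self.motion_streamnet = _SkeletonStream(coord_dim, joints, config.conv_channels, rng)
        self.fuse = nn.Linear(2 * config.conv_channels[-1], config.hidden_dim, rng)

    @property
    def hidden_dim(self) -> int:
        return self.config.hidden_dim

    def forward(self, x) -> Tensor:
        if isinstance(x, Tensor):
            x = x.data
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 4:
            raise ValueError("skeleton batch must have shape (n, C, T, V)")
        if x.shape[1] != self.coord_dim or x.shape[3] != self.joints:
            raise ValueError("skeleton batch does not match encoder geometry")
        if x.shape[2] < 2:
            raise ValueError("skeleton sequences need at least 2 frames")
        hj = self.joint_stream(Tensor(x))
        hm = self.motion_streamnet(Tensor(motion_stream(x)))
        return self.fuse(concatenate([hj, hm], axis=1))


class Projector(nn.Module):
    """MLP projection head: batch norm + ReLU between layers, linear last."""

    def __init__(self, in_dim: int, config: ProjectorConfig, rng: np.random.Generator):
        super().__init__()
        config.validate()
        self.config = config
        layers: list[nn.Module] = []
        prev = in_dim
        for dim in config.layer_dims[:-1]:
            layers += [nn.Linear(prev, dim, rng), nn.BatchNorm(dim), nn.ReLU()]
            prev = dim
        layers.append(nn.Linear(prev, config.layer_dims[-1], rng))
        self.net = nn.Sequential(*layers)

    @property
    def embedding_dim(self) -> int:
        return self.config.embedding_dim

    def forward(self, x) -> Tensor:
        return self.net(_lift(x))
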