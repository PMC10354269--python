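"""Self-supervised pretraining loops.

Two scikit-learn style estimators:

* :class:`BarlowTwinsPretrainer` — unimodal two-view pretraining.  Each
  batch is augmented twice, both views pass through the *same* encoder and
  projection head, and the redundancy-reduction loss drives the
  between-view cross-correlation matrix toward the identity.

* :class:`VICRegPretrainer` — multimodal pretraining.  Each paired sample
  contributes one augmented view per modality; modality-specific encoders
  and projection heads (no weight sharing) are optimised jointly under the
  variance/invariance/covariance objective.

Neither loop ever reads labels; batches are shuffled per epoch and the
last incomplete batch is dropped because both losses are batch-statistics
based.  All randomness (initialisation, shuffling, augmentation) derives
from the ``seed`` parameter, so training is exactly reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .augment import (AugmentationSpec, default_imu_pipeline,
                      default_skeleton_pipeline, make_view_pair,
                      multimodal_imu_pipeline, multimodal_skeleton_pipeline)
from .autograd import no_grad
from .encoders import (IMUEncoder, IMUEncoderConfig, Projector,
                       ProjectorConfig, SkeletonEncoder, SkeletonEncoderConfig)
from .losses import LossWeights, barlow_loss, cross_correlation, vicreg_loss
from .optim import Adam
from .synthetic import LabeledSample

__all__ = [
    "SMALL_IMU_CONFIG",
    "SMALL_SKELETON_CONFIG",
    "SMALL_PROJECTOR_CONFIG",
    "BarlowTwinsPretrainer",
    "VICRegPretrainer",
    "pretrain_unimodal",
    "pretrain_multimodal",
    "lambda_mu_grid",
    "save_checkpoint",
    "load_checkpoint",
]

# Desk-scale preset: narrow encoders and a 32-dimensional embedding, sized
# so a full 50-epoch pretraining run completes in minutes on one CPU core.
SMALL_IMU_CONFIG = IMUEncoderConfig(conv_channels=(16, 32, 64), model_dim=64)
SMALL_SKELETON_CONFIG = SkeletonEncoderConfig(conv_channels=(8, 8, 8, 16, 16, 32), hidden_dim=64)
SMALL_PROJECTOR_CONFIG = ProjectorConfig(layer_dims=(64, 32))


def _check_samples(X: Sequence[LabeledSample], need_skeleton: bool, need_imu: bool):
    if len(X) == 0:
        raise ValueError("empty training set")
    for s in X:
        if need_skeleton and getattr(s, "skeleton", None) is None:
            raise ValueError("sample without a skeleton modality encountered")
        if need_imu and getattr(s, "imu", None) is None:
            raise ValueError("unpaired sample: missing IMU modality")


def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    """Shuffled batch index lists, dropping the last incomplete batch."""
    order = rng.permutation(n)
    for start in range(0, n - batch_size + 1, batch_size):
        yield order[start : start + batch_size]


class BarlowTwinsPretrainer(BaseEstimator, TransformerMixin):
    """Unimodal negative-free pretraining with the redundancy-reduction loss.

    Parameters
    ----------
    modality : "skeleton" or "imu".
    encoder_config, projector_config : architecture descriptions; defaults
        are the desk-scale preset.
    beta : off-diagonal weight of the loss.
    learning_rate, epochs, batch_size, seed : optimisation settings.
    pipeline : augmentation pipeline for the modality (two independent
        draws per sample form the view pair).
    center_correlation : mean-centre embeddings before the correlation.
    """

    def __init__(
        self,
        modality: str = "skeleton",
        encoder_config=None,
        projector_config=None,
        beta: float = 0.005,
        learning_rate: float = 1e-2,
        epochs: int = 50,
        batch_size: int = 32,
        seed: int = 28,
        pipeline: list[AugmentationSpec] | None = None,
        center_correlation: bool = True,
    ):
        self.modality = modality
        self.encoder_config = encoder_config
        self.projector_config = projector_config
        self.beta = beta
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.pipeline = pipeline
        self.center_correlation = center_correlation

    # -- construction -----------------------------------------------------

    def _build(self, X: Sequence[LabeledSample]) -> None:
        if self.modality not in ("skeleton", "imu"):
            raise ValueError("modality must be 'skeleton' or 'imu'")
        if self.batch_size < 2:
            raise ValueError("batch_size must be at least 2")
        if self.epochs < 1:
            raise ValueError("epochs must be at least 1")
        init_rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0]))
        proj_cfg = self.projector_config or SMALL_PROJECTOR_CONFIG
        if self.modality == "skeleton":
            cfg = self.encoder_config or SMALL_SKELETON_CONFIG
            C, _, V = X[0].skeleton.shape
            self.encoder_ = SkeletonEncoder(C, V, cfg, init_rng)
        else:
            cfg = self.encoder_config or SMALL_IMU_CONFIG
            S = X[0].imu.shape[1]
            self.encoder_ = IMUEncoder(S, cfg, init_rng)
        self.projector_ = Projector(self.encoder_.hidden_dim, proj_cfg, init_rng)
        self._opt = Adam(self.encoder_.parameters() + self.projector_.parameters(),
                         lr=self.learning_rate)
        self._rng = np.random.default_rng(np.random.SeedSequence([self.seed, 1]))
        self.loss_history_ = []

    def _default_pipeline(self, X) -> list[AugmentationSpec]:
        if self.pipeline is not None:
            return self.pipeline
        if self.modality == "skeleton":
            return default_skeleton_pipeline()
        S = X[0].imu.shape[1]
        return default_imu_pipeline(with_rotation=(S % 3 == 0))

    # -- training ---------------------------------------------------------

    def fit(self, X: Sequence[LabeledSample], y=None) -> "BarlowTwinsPretrainer":
        X = list(X)
        _check_samples(X, self.modality == "skeleton", self.modality == "imu")
        if self.batch_size > len(X):
            raise ValueError("batch_size exceeds the dataset size")
        self._build(X)
        return self.continue_fit(X, self.epochs)

    def continue_fit(self, X: Sequence[LabeledSample], epochs: int) -> "BarlowTwinsPretrainer":
        X = list(X)
        pipe = self._default_pipeline(X)
        mode = f"unimodal_{self.modality}"
        skel_pipe = pipe if self.modality == "skeleton" else None
        imu_pipe = pipe if self.modality == "imu" else None
        self.encoder_.train()
        self.projector_.train()
        for _ in range(epochs):
            losses = []
            for batch in _epoch_batches(len(X), self.batch_size, self._rng):
                va, vb = [], []
                for i in batch:
                    a, b = make_view_pair(X[i], skel_pipe, imu_pipe, self._rng, mode=mode)
                    va.append(a)
                    vb.append(b)
                za = self.projector_(self.encoder_(np.stack(va)))
                zb = self.projector_(self.encoder_(np.stack(vb)))
                loss = barlow_loss(
                    cross_correlation(za, zb, center=self.center_correlation),
                    self.beta,
                )
                self._opt.zero_grad()
                loss.backward()
                self._opt.step()
                losses.append(loss.item())
            self.loss_history_.append(float(np.mean(losses)))
        return self

    # -- inference --------------------------------------------------------

    def transform(self, X: Sequence[LabeledSample]) -> np.ndarray:
        """Hidden features of the unaugmented modality, shape (n, d_h)."""
        self.encoder_.eval()
        data = np.stack([s.skeleton if self.modality == "skeleton" else s.imu for s in X])
        with no_grad():
            return self.encoder_(data).data

    def embed(self, X: Sequence[LabeledSample]) -> np.ndarray:
        """Projected embeddings, shape (n, d)."""
        self.encoder_.eval()
        self.projector_.eval()
        data = np.stack([s.skeleton if self.modality == "skeleton" else s.imu for s in X])
        with no_grad():
            return self.projector_(self.encoder_(data)).data


class VICRegPretrainer(BaseEstimator, TransformerMixin):
    """Multimodal pretraining under the variance/invariance/covariance loss.

    The skeleton and IMU branches have independent encoders and projection
    heads updated jointly; the invariance term ties the two modalities'
    embeddings of the same action instance together while the variance and
    covariance terms prevent collapse.
    """

    def __init__(
        self,
        imu_config=None,
        skeleton_config=None,
        projector_config=None,
        loss_weights: LossWeights = LossWeights(),
        learning_rate: float = 1e-2,
        epochs: int = 50,
        batch_size: int = 32,
        seed: int = 28,
        skeleton_pipeline: list[AugmentationSpec] | None = None,
        imu_pipeline: list[AugmentationSpec] | None = None,
        invariance_scale: str = "per_element",
    ):
        self.imu_config = imu_config
        self.skeleton_config = skeleton_config
        self.projector_config = projector_config
        self.loss_weights = loss_weights
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.skeleton_pipeline = skeleton_pipeline
        self.imu_pipeline = imu_pipeline
        self.invariance_scale = invariance_scale

    def _build(self, X: Sequence[LabeledSample]) -> None:
        if self.batch_size < 2:
            raise ValueError("batch_size must be at least 2")
        if self.epochs < 1:
            raise ValueError("epochs must be at least 1")
        self.loss_weights.validate()
        init_rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0]))
        C, _, V = X[0].skeleton.shape
        S = X[0].imu.shape[1]
        proj_cfg = self.projector_config or SMALL_PROJECTOR_CONFIG
        self.skeleton_encoder_ = SkeletonEncoder(
            C, V, self.skeleton_config or SMALL_SKELETON_CONFIG, init_rng)
        self.imu_encoder_ = IMUEncoder(S, self.imu_config or SMALL_IMU_CONFIG, init_rng)
        self.skeleton_projector_ = Projector(self.skeleton_encoder_.hidden_dim, proj_cfg, init_rng)
        self.imu_projector_ = Projector(self.imu_encoder_.hidden_dim, proj_cfg, init_rng)
        params = (self.skeleton_encoder_.parameters() + self.imu_encoder_.parameters()
                  + self.skeleton_projector_.parameters() + self.imu_projector_.parameters())
        self._opt = Adam(params, lr=self.learning_rate)
        self._rng = np.random.default_rng(np.random.SeedSequence([self.seed, 1]))
        self.history_ = pd.DataFrame(columns=["epoch", "total", "s", "v", "c"])
        self.step_log_ = pd.DataFrame(columns=["step", "total", "s", "v", "c"])
        self._step = 0

    def fit(self, X: Sequence[LabeledSample], y=None) -> "VICRegPretrainer":
        X = list(X)
        _check_samples(X, True, True)
        if self.batch_size > len(X):
            raise ValueError("batch_size exceeds the dataset size")
        self._build(X)
        return self.continue_fit(X, self.epochs)

    def continue_fit(self, X: Sequence[LabeledSample], epochs: int) -> "VICRegPretrainer":
        X = list(X)
        skel_pipe = (self.skeleton_pipeline if self.skeleton_pipeline is not None
                     else multimodal_skeleton_pipeline())
        S = X[0].imu.shape[1]
        imu_pipe = (self.imu_pipeline if self.imu_pipeline is not None
                    else multimodal_imu_pipeline(with_rotation=(S % 3 == 0)))
        modules = (self.skeleton_encoder_, self.imu_encoder_,
                   self.skeleton_projector_, self.imu_projector_)
        for m in modules:
            m.train()
        w = self.loss_weights
        trivial = w.lam == 0 and w.mu == 0 and w.phi == 0
        step_rows, epoch_rows = [], []
        for _ in range(epochs):
            ep_stats = []
            for batch in _epoch_batches(len(X), self.batch_size, self._rng):
                vs, vi = [], []
                for i in batch:
                    a, b = make_view_pair(X[i], skel_pipe, imu_pipe, self._rng,
                                          mode="multimodal")
                    vs.append(a)
                    vi.append(b)
                zs = self.skeleton_projector_(self.skeleton_encoder_(np.stack(vs)))
                zi = self.imu_projector_(self.imu_encoder_(np.stack(vi)))
                total, comp = vicreg_loss(zs, zi, w,
                                          invariance_scale=self.invariance_scale)
                if not trivial:  # a zero objective has no gradients to apply
                    self._opt.zero_grad()
                    total.backward()
                    self._opt.step()
                row = (self._step, total.item(), comp["s"].item(),
                       comp["v"].item(), comp["c"].item())
                step_rows.append(row)
                ep_stats.append(row[1:])
                self._step += 1
            mean = np.mean(ep_stats, axis=0)
            epoch_rows.append((len(self.history_) + len(epoch_rows), *mean))
        self.step_log_ = pd.concat(
            [self.step_log_, pd.DataFrame(step_rows, columns=self.step_log_.columns)],
            ignore_index=True) if len(self.step_log_) else pd.DataFrame(
                step_rows, columns=["step", "total", "s", "v", "c"])
        new_hist = pd.DataFrame(epoch_rows, columns=["epoch", "total", "s", "v", "c"])
        self.history_ = (pd.concat([self.history_, new_hist], ignore_index=True)
                         if len(self.history_) else new_hist)
        return self

    # -- inference --------------------------------------------------------

    def encode_skeleton(self, X: Sequence[LabeledSample]) -> np.ndarray:
        self.skeleton_encoder_.eval()
        with no_grad():
            return self.skeleton_encoder_(np.stack([s.skeleton for s in X])).data

    def encode_imu(self, X: Sequence[LabeledSample]) -> np.ndarray:
        self.imu_encoder_.eval()
        with no_grad():
            return self.imu_encoder_(np.stack([s.imu for s in X])).data

    def transform(self, X: Sequence[LabeledSample]) -> np.ndarray:
        """Concatenated (skeleton, IMU) hidden features."""
        return np.concatenate([self.encode_skeleton(X), self.encode_imu(X)], axis=1)

    def embeddings(self, X: Sequence[LabeledSample]) -> tuple[np.ndarray, np.ndarray]:
        """Projected embeddings (Z_skeleton, Z_imu) in evaluation mode."""
        for m in (self.skeleton_encoder_, self.imu_encoder_,
                  self.skeleton_projector_, self.imu_projector_):
            m.eval()
        with no_grad():
            zs = self.skeleton_projector_(
                self.skeleton_encoder_(np.stack([s.skeleton for s in X]))).data
            zi = self.imu_projector_(
                self.imu_encoder_(np.stack([s.imu for s in X]))).data
        return zs, zi


def lambda_mu_grid(train_data, values: Sequence[float] = (5.0, 10.0, 25.0),
                   **kwargs) -> pd.DataFrame:
    """Fit one multimodal pretrainer per λ = μ value (φ stays fixed) and
    tabulate the final loss components and mean embedding standard
    deviations — the operating condition is λ = μ > 1 with φ = 1."""
    base = kwargs.pop("loss_weights", LossWeights())
    rows = []
    for value in values:
        w = LossWeights(beta=base.beta, lam=float(value), mu=float(value),
                        phi=base.phi, gamma=base.gamma, eps=base.eps)
        est = VICRegPretrainer(loss_weights=w, **kwargs).fit(train_data)
        zs, zi = est.embeddings(train_data)
        last = est.history_.iloc[-1]
        rows.append({"lam_mu": float(value), "total": last.total, "s": last.s,
                     "v": last.v, "c": last.c,
                     "std_skeleton": zs.std(axis=0, ddof=1).mean(),
                     "std_imu": zi.std(axis=0, ddof=1).mean()})
    return pd.DataFrame(rows)


def pretrain_unimodal(train_data, **kwargs) -> tuple[object, object, list[float]]:
    """Functional wrapper: returns (encoder, projector, loss history)."""
    est = BarlowTwinsPretrainer(**kwargs).fit(train_data)
    return est.encoder_, est.projector_, est.loss_history_


def pretrain_multimodal(train_data, **kwargs):
    """Functional wrapper: returns the fitted :class:`VICRegPretrainer`."""
    return VICRegPretrainer(**kwargs).fit(train_data)


# -- checkpointing ---------------------------------------------------------

_CHECKPOINT_VERSION = 1


def _module_states(est) -> dict[str, np.ndarray]:
    out = {}
    for name in ("encoder_", "projector_", "skeleton_encoder_", "imu_encoder_",
                 "skeleton_projector_", "imu_projector_"):
        mod = getattr(est, name, None)
        if mod is not None:
            for k, v in mod.state_dict().items():
                out[f"{name}/{k}"] = v
    return out


def save_checkpoint(est, path: str | Path) -> None:
    """Serialise a fitted pretrainer: weights + optimiser + rng state, with
    a JSON sidecar echoing the configuration and a version tag."""
    path = Path(path)
    arrays = _module_states(est)
    opt = est._opt.state_dict()
    for i, m in enumerate(opt["m"]):
        arrays[f"__opt_m/{i}"] = m
    for i, v in enumerate(opt["v"]):
        arrays[f"__opt_v/{i}"] = v
    np.savez(path, **arrays)
    meta = {
        "version": _CHECKPOINT_VERSION,
        "class": type(est).__name__,
        "params": {k: repr(v) for k, v in est.get_params().items()},
        "opt_t": opt["t"],
        "rng_state": est._rng.bit_generator.state,
        "history": (est.loss_history_ if hasattr(est, "loss_history_")
                    else {"epochs": est.history_.to_dict(orient="list"),
                          "steps": est.step_log_.to_dict(orient="list")}),
        "step": getattr(est, "_step", None),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(est, path: str | Path, X: Sequence[LabeledSample]):
    """Restore weights, optimiser and rng state into a freshly constructed
    estimator with the *same* constructor arguments; ``X`` supplies the data
    geometry.  Returns the estimator ready for :meth:`continue_fit`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    if meta["version"] != _CHECKPOINT_VERSION:
        raise ValueError("unsupported checkpoint version")
    est._build(list(X))
    with np.load(path) as data:
        arrays = {k: data[k] for k in data.files}
    for name in ("encoder_", "projector_", "skeleton_encoder_", "imu_encoder_",
                 "skeleton_projector_", "imu_projector_"):
        mod = getattr(est, name, None)
        if mod is not None:
            prefix = f"{name}/"
            state = {k[len(prefix):]: v for k, v in arrays.items() if k.startswith(prefix)}
            mod.load_state_dict(state)
    n_params = len(est._opt.params)
    est._opt.load_state_dict({
        "t": meta["opt_t"],
        "m": [arrays[f"__opt_m/{i}"] for i in range(n_params)],
        "v": [arrays[f"__opt_v/{i}"] for i in range(n_params)],
    })
    est._rng.bit_generator.state = meta["rng_state"]
    if isinstance(meta["history"], list):
        est.loss_history_ = list(meta["history"])
    else:
        est.history_ = pd.DataFrame(meta["history"]["epochs"])
        est.step_log_ = pd.DataFrame(meta["history"]["steps"])
        est._step = meta["step"]
    return est
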