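"""Frozen-encoder fine-tuning and the three evaluation protocols.

The classifier head mirrors standard multimodal fusion fine-tuning: each
modality's frozen hidden features pass through a linear map to a common
width (256 by default) with batch normalisation and ReLU, the modality
branches are concatenated, and a final linear layer with softmax predicts
the action class.  Only the head is trained; the encoders never receive
gradients.

Protocols
---------
* linear evaluation — fit the head on the full labelled training split,
  report accuracy, macro-F1 and the row-normalised confusion matrix;
* semi-supervised — repeat fine-tuning on stratified label fractions
  p ∈ {1, 5, 10, 25, 50}%, reporting per-p means with Student-t
  confidence intervals over repeats;
* zero-shot class masking — pretrain with chosen classes excluded, then
  fine-tune and test on all classes, reporting recall on the held-out
  classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import accuracy_score, f1_score

from . import nn
from .autograd import no_grad
from .optim import Adam
from .synthetic import LabeledSample

__all__ = [
    "FusionHeadConfig",
    "ProtocolConfig",
    "EvalReport",
    "FusionClassifier",
    "CachedFeatures",
    "cache_features",
    "linear_evaluate",
    "semi_supervised_protocol",
    "zero_shot_protocol",
    "normalized_confusion",
    "embed_2d",
    "t_ci_halfwidth",
]


@dataclass(frozen=True)
class FusionHeadConfig:
    per_modality_dim: int = 256
    epochs: int = 100
    learning_rate: float = 1e-3  # one-tenth of the pretraining rate
    batch_size: int = 64
    seed: int = 0

    def validate(self) -> None:
        if self.per_modality_dim < 1:
            raise ValueError("per_modality_dim must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass(frozen=True)
class ProtocolConfig:
    label_fractions: tuple[float, ...] = (0.01, 0.05, 0.10, 0.25, 0.50)
    repeats: int = 10
    hidden_classes: tuple[int, ...] = (1, 2, 5)  # 1-based, as conventionally printed
    finetune_epochs: int = 100
    confidence_level: float = 0.95
    seed: int = 0

    def validate(self) -> None:
        if any(not 0 < p <= 1 for p in self.label_fractions):
            raise ValueError("label fractions must lie in (0, 1]")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not 0 < self.confidence_level < 1:
            raise ValueError("confidence_level must lie in (0, 1)")


@dataclass
class EvalReport:
    accuracy: float
    macro_f1: float
    confusion: np.ndarray
    num_classes: int
    n_test: int
    warnings: list[str] = field(default_factory=list)
    per_class_recall: np.ndarray | None = None


class _FusionHead(nn.Module):
    def __init__(self, in_dims: list[int], num_classes: int, width: int,
                 rng: np.random.Generator):
        super().__init__()
        self.branches = [
            nn.Sequential(nn.Linear(d, width, rng), nn.BatchNorm(width), nn.ReLU())
            for d in in_dims
        ]
        self.classifier = nn.Linear(width * len(in_dims), num_classes, rng)

    def forward_multi(self, feats):
        from .autograd import Tensor, concatenate
        feats = [f if isinstance(f, Tensor) else Tensor(np.asarray(f, dtype=np.float64))
                 for f in feats]
        outs = [branch(f) for branch, f in zip(self.branches, feats)]
        h = outs[0] if len(outs) == 1 else concatenate(outs, axis=1)
        return self.classifier(h)


class FusionClassifier(BaseEstimator, ClassifierMixin):
    """Softmax classifier over one or two frozen encoders.

    ``encoders`` maps modality name ("skeleton", "imu") to any object with
    a scikit-learn style encode method: a fitted pretrainer's encoder, or
    the pretrainer itself via ``feature_fn``.  To stay agnostic, the
    classifier takes callables: ``feature_fns`` is a dict
    ``{modality: callable(samples) -> (n, d_h) array}`` whose outputs are
    treated as frozen features.
    """

    def __init__(self, feature_fns: dict, head_config: FusionHeadConfig = FusionHeadConfig()):
        self.feature_fns = feature_fns
        self.head_config = head_config

    def _features(self, X: Sequence[LabeledSample]) -> list[np.ndarray]:
        if not self.feature_fns:
            raise ValueError("at least one modality feature function is required")
        return [np.asarray(fn(X), dtype=np.float64)
                for _, fn in sorted(self.feature_fns.items())]

    def fit(self, X: Sequence[LabeledSample], y=None) -> "FusionClassifier":
        cfg = self.head_config
        cfg.validate()
        X = list(X)
        if y is None:
            y = [s.label for s in X]
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        num_classes = int(self.classes_.max()) + 1
        feats = self._features(X)
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
        self.head_ = _FusionHead([f.shape[1] for f in feats], num_classes,
                                 cfg.per_modality_dim, rng)
        opt = Adam(self.head_.parameters(), lr=cfg.learning_rate)
        n = len(X)
        bs = min(cfg.batch_size, n)
        self.head_.train()
        self.loss_history_ = []
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                if len(idx) < 2:
                    continue  # batch norm needs at least two rows
                logits = self.head_.forward_multi([f[idx] for f in feats])
                loss = nn.cross_entropy(logits, y[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(loss.item())
            self.loss_history_.append(float(np.mean(losses)))
        return self

    def predict_proba(self, X: Sequence[LabeledSample]) -> np.ndarray:
        self.head_.eval()
        feats = self._features(list(X))
        with no_grad():
            logits = self.head_.forward_multi(feats)
            return nn.softmax(logits).data

    def predict(self, X: Sequence[LabeledSample]) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    def score(self, X, y=None) -> float:
        if y is None:
            y = [s.label for s in X]
        return float(accuracy_score(np.asarray(y), self.predict(X)))


class CachedFeatures:
    """Memoising wrapper for a feature function.

    Caches per-sample hidden vectors (keyed by sample identity) so the
    repeated head fits of the protocols encode every sequence exactly
    once.  Valid because encoders run in evaluation mode, where features
    are independent of batch composition.
    """

    def __init__(self, fn):
        self.fn = fn
        self._cache: dict[int, tuple[LabeledSample, np.ndarray]] = {}

    def __call__(self, samples: Sequence[LabeledSample]) -> np.ndarray:
        missing = [s for s in samples if id(s) not in self._cache]
        if missing:
            arr = np.asarray(self.fn(missing))
            for s, v in zip(missing, arr):
                self._cache[id(s)] = (s, v)
        return np.stack([self._cache[id(s)][1] for s in samples])


def cache_features(feature_fns: dict) -> dict:
    """Wrap every modality feature function with :class:`CachedFeatures`."""
    return {k: (fn if isinstance(fn, CachedFeatures) else CachedFeatures(fn))
            for k, fn in feature_fns.items()}


def normalized_confusion(labels, predictions, num_classes: int) -> np.ndarray:
    """Row-normalised confusion matrix: row i holds the distribution of
    predictions for true class i; rows with no test samples stay zero."""
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    if labels.size and (labels.min() < 0 or labels.max() >= num_classes
                        or predictions.min() < 0 or predictions.max() >= num_classes):
        raise ValueError("class index out of range")
    counts = np.zeros((num_classes, num_classes))
    np.add.at(counts, (labels, predictions), 1.0)
    sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        out = np.where(sums > 0, counts / np.maximum(sums, 1), 0.0)
    return out


def _report(y_true, y_pred, num_classes: int, warnings: list[str]) -> EvalReport:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    acc = float(accuracy_score(y_true, y_pred))
    f1 = float(f1_score(y_true, y_pred, average="macro",
                        labels=np.arange(num_classes), zero_division=0))
    conf = normalized_confusion(y_true, y_pred, num_classes)
    # Internal consistency: accuracy must equal the trace of the raw
    # confusion counts over n.
    counts = np.zeros((num_classes, num_classes))
    np.add.at(counts, (y_true, y_pred), 1.0)
    assert abs(np.trace(counts) / max(len(y_true), 1) - acc) < 1e-12
    recall = np.full(num_classes, np.nan)
    for k in range(num_classes):
        m = y_true == k
        if m.any():
            recall[k] = float((y_pred[m] == k).mean())
    return EvalReport(accuracy=acc, macro_f1=f1, confusion=conf,
                      num_classes=num_classes, n_test=len(y_true),
                      warnings=warnings, per_class_recall=recall)


def linear_evaluate(
    feature_fns: dict,
    train: Sequence[LabeledSample],
    test: Sequence[LabeledSample],
    head_config: FusionHeadConfig = FusionHeadConfig(),
) -> EvalReport:
    """Fine-tune only the fusion head on ``train`` and evaluate on ``test``."""
    train, test = list(train), list(test)
    all_labels = [s.label for s in train] + [s.label for s in test]
    num_classes = int(max(all_labels)) + 1
    warnings = []
    missing = sorted(set(range(num_classes)) - {s.label for s in train})
    if missing:
        warnings.append(f"classes absent from the labelled training set: {missing}")
    feature_fns = cache_features(feature_fns)
    clf = FusionClassifier(feature_fns, head_config).fit(train)
    return _report([s.label for s in test], clf.predict(test), num_classes, warnings)


def t_ci_halfwidth(values: np.ndarray, confidence_level: float = 0.95) -> float:
    """Student-t confidence-interval half width of the mean of ``values``."""
    values = np.asarray(values, dtype=float)
    r = len(values)
    if r < 2:
        return float("nan")
    tcrit = stats.t.ppf(0.5 + confidence_level / 2.0, df=r - 1)
    return float(tcrit * values.std(ddof=1) / np.sqrt(r))


def _stratified_fraction(labels: np.ndarray, p: float, rng: np.random.Generator):
    """Indices of a stratified p-fraction, at least one sample per class."""
    idx = []
    floored = []
    for k in np.unique(labels):
        pool = np.flatnonzero(labels == k)
        n_k = int(round(p * len(pool)))
        if n_k == 0:
            n_k = 1
            floored.append(int(k))
        idx.extend(rng.choice(pool, size=n_k, replace=False).tolist())
    return np.array(sorted(idx)), floored


def semi_supervised_protocol(
    feature_fns: dict,
    train: Sequence[LabeledSample],
    test: Sequence[LabeledSample],
    config: ProtocolConfig = ProtocolConfig(),
    head_config: FusionHeadConfig = FusionHeadConfig(),
) -> pd.DataFrame:
    """Label-fraction sweep: for each p, fine-tune the head ``repeats``
    times on fresh stratified label draws and aggregate the test metrics.

    Returns a table with one row per fraction: mean accuracy, mean macro
    F1, and Student-t confidence-interval half widths over the repeats.
    """
    config.validate()
    feature_fns = cache_features(feature_fns)
    train, test = list(train), list(test)
    labels = np.array([s.label for s in train])
    num_classes = int(max(max(labels), max(s.label for s in test))) + 1
    y_test = [s.label for s in test]
    rows = []
    for p in config.label_fractions:
        accs, f1s = [], []
        for rep in range(config.repeats):
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, int(round(p * 10000)), rep]))
            if p == 1.0:
                # Degenerate case: the full labelled set needs no sampling,
                # so this reduces exactly to linear evaluation.
                subset = train
                head_seed = head_config.seed
            else:
                idx, _ = _stratified_fraction(labels, p, rng)
                subset = [train[i] for i in idx]
                head_seed = int(rng.integers(2**31))
            hc = FusionHeadConfig(
                per_modality_dim=head_config.per_modality_dim,
                epochs=config.finetune_epochs,
                learning_rate=head_config.learning_rate,
                batch_size=head_config.batch_size,
                seed=head_seed,
            )
            clf = FusionClassifier(feature_fns, hc).fit(subset)
            pred = clf.predict(test)
            accs.append(accuracy_score(y_test, pred))
            f1s.append(f1_score(y_test, pred, average="macro",
                                labels=np.arange(num_classes), zero_division=0))
        rows.append({
            "p": p,
            "mean_accuracy": float(np.mean(accs)),
            "mean_macro_f1": float(np.mean(f1s)),
            "ci_accuracy": t_ci_halfwidth(np.array(accs), config.confidence_level),
            "ci_macro_f1": t_ci_halfwidth(np.array(f1s), config.confidence_level),
            "repeats": config.repeats,
        })
    return pd.DataFrame(rows)


def zero_shot_protocol(
    train: Sequence[LabeledSample],
    test: Sequence[LabeledSample],
    hidden_classes: Sequence[int],
    pretrainer,
    head_config: FusionHeadConfig = FusionHeadConfig(),
) -> tuple[EvalReport, dict[int, float]]:
    """Class-masking protocol.

    Samples of ``hidden_classes`` (1-based indices, converted internally)
    are excluded from pretraining only; fine-tuning and testing use all
    classes.  Returns the overall report and per-hidden-class recall.
    """
    train, test = list(train), list(test)
    classes = sorted({s.label for s in train})
    hidden0 = sorted({h - 1 for h in hidden_classes})
    if any(h not in classes for h in hidden0):
        raise ValueError("hidden_classes must reference observed classes")
    if set(hidden0) >= set(classes):
        raise ValueError("hidden_classes cannot cover every class")
    visible = [s for s in train if s.label not in hidden0]
    pretrainer.fit(visible)
    feature_fns = {
        "skeleton": pretrainer.encode_skeleton,
        "imu": pretrainer.encode_imu,
    }
    report = linear_evaluate(feature_fns, train, test, head_config)
    hidden_recall = {h + 1: float(report.per_class_recall[h]) for h in hidden0}
    return report, hidden_recall


def embed_2d(embeddings: np.ndarray, seed: int = 0) -> np.ndarray:
    """2-D t-SNE coordinates for report scatter plots."""
    from sklearn.manifold import TSNE

    embeddings = np.asarray(embeddings, dtype=np.float64)
    n = embeddings.shape[0]
    if n < 5:
        raise ValueError("t-SNE embedding requires at least 5 points")
    perplexity = min(30.0, (n - 1) / 3.0)
    tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca")
    return tsne.fit_transform(embeddings)
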