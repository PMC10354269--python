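"""Negative-free contrastive objectives.

Two families are implemented, both operating on an n×d batch of projected
embeddings and both avoiding negative pairs by regularising batch
statistics instead:

* the **redundancy-reduction** objective: drive the between-view
  cross-correlation matrix toward the identity — unit diagonal makes the
  embedding invariant to the augmentation, zero off-diagonals decorrelate
  the embedding dimensions;
* the **variance/invariance/covariance** objective: a hinge keeping every
  embedding dimension's batch standard deviation above a target γ (the
  anti-collapse term), the mean squared distance between the paired
  embeddings, and the squared off-diagonal entries of each batch's
  covariance matrix.

All functions accept either plain numpy arrays (returning floats/arrays)
or autograd tensors (returning tensors on the tape), so the same code path
is exercised by the training loops and by the analytic unit checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor

__all__ = [
    "LossWeights",
    "cross_correlation",
    "barlow_loss",
    "variance_term",
    "invariance_term",
    "covariance_term",
    "vicreg_loss",
]

_NORM_FLOOR = 1e-12


@dataclass(frozen=True)
class LossWeights:
    """Trade-off weights for the two objectives.

    ``beta`` weighs the off-diagonal term of the redundancy-reduction loss;
    ``lam``/``mu``/``phi`` weigh invariance, variance and covariance;
    ``gamma`` is the target batch standard deviation of the hinge and
    ``eps`` the stabiliser inside its square root.
    """

    beta: float = 0.005
    lam: float = 25.0
    mu: float = 25.0
    phi: float = 1.0
    gamma: float = 1.0
    eps: float = 1e-4

    def validate(self) -> None:
        for name in ("beta", "lam", "mu", "phi", "gamma", "eps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _as_tensor(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float64)), False


def _unwrap(t: Tensor, keep: bool):
    if keep:
        return t
    return t.item() if t.data.size == 1 else t.data.copy()


def _check_batch(Z: Tensor, name: str) -> None:
    if Z.ndim != 2:
        raise ValueError(f"{name} must be a 2-D n×d batch")
    if Z.shape[0] < 2:
        raise ValueError(f"{name} needs a batch of at least 2 embeddings")


def cross_correlation(Za, Zb, center: bool = True, strict: bool = False):
    """Between-view cross-correlation matrix, shape d×d.

    Columns are mean-centred over the batch (toggleable), then
    ``C[i, j] = <Za[:, i], Zb[:, j]> / (||Za[:, i]|| * ||Zb[:, j]||)``.
    Column norms are floored at 1e-12; with ``strict=True`` an exactly
    collapsed (zero-norm) column raises instead.
    """
    Za, wa = _as_tensor(Za)
    Zb, wb = _as_tensor(Zb)
    _check_batch(Za, "Za")
    _check_batch(Zb, "Zb")
    if Za.shape != Zb.shape:
        raise ValueError("Za and Zb must have the same shape")
    if center:
        Za = Za - Za.mean(axis=0, keepdims=True)
        Zb = Zb - Zb.mean(axis=0, keepdims=True)
    na2 = (Za**2).sum(axis=0)
    nb2 = (Zb**2).sum(axis=0)
    if strict and (np.any(na2.data < _NORM_FLOOR**2) or np.any(nb2.data < _NORM_FLOOR**2)):
        raise ValueError("embedding collapse: a column has (near-)zero norm")
    # max(norm, floor) = floor + relu(norm - floor): keeps the tape intact.
    na = _NORM_FLOOR + (na2.sqrt() - _NORM_FLOOR).relu()
    nb = _NORM_FLOOR + (nb2.sqrt() - _NORM_FLOOR).relu()
    d = Za.shape[1]
    C = (Za.transpose(1, 0) @ Zb) / (na.reshape(d, 1) * nb.reshape(1, d))
    return C if (wa or wb) else C.data.copy()


def barlow_loss(C, beta: float = 0.005):
    """Redundancy-reduction loss of a d×d correlation matrix:
    ``sum_i (1 - C_ii)^2 + beta * sum_{i != j} C_ij^2``."""
    C, wrapped = _as_tensor(C)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("C must be a square matrix")
    eye = np.eye(C.shape[0])
    on_diag = (((1.0 - C) * Tensor(eye)) ** 2).sum()
    off_diag = ((C * Tensor(1.0 - eye)) ** 2).sum()
    return _unwrap(on_diag + beta * off_diag, wrapped)


def variance_term(Z, gamma: float = 1.0, eps: float = 1e-4):
    """Hinge on per-dimension batch standard deviation:
    ``mean_j max(0, gamma - sqrt(Var(Z[:, j]) + eps))`` with the unbiased
    (n-1) variance."""
    Z, wrapped = _as_tensor(Z)
    _check_batch(Z, "Z")
    n, d = Z.shape
    mean = Z.mean(axis=0, keepdims=True)
    var = ((Z - mean) ** 2).sum(axis=0) * (1.0 / (n - 1))
    std = (var + eps).sqrt()
    hinge = (gamma - std).relu()
    return _unwrap(hinge.mean(), wrapped)


def invariance_term(Za, Zb):
    """Mean squared Euclidean distance between paired embeddings."""
    Za, wa = _as_tensor(Za)
    Zb, wb = _as_tensor(Zb)
    if Za.shape != Zb.shape:
        raise ValueError("Za and Zb must have the same shape")
    n = Za.shape[0]
    return _unwrap(((Za - Zb) ** 2).sum() * (1.0 / n), wa or wb)


def covariance_term(Z):
    """Mean squared off-diagonal entry of the batch covariance matrix,
    scaled by 1/d: ``(1/d) * sum_{i != j} Cov(Z)_{ij}^2``."""
    Z, wrapped = _as_tensor(Z)
    _check_batch(Z, "Z")
    n, d = Z.shape
    Zc = Z - Z.mean(axis=0, keepdims=True)
    cov = (Zc.transpose(1, 0) @ Zc) * (1.0 / (n - 1))
    off = cov * Tensor(1.0 - np.eye(d))
    return _unwrap((off**2).sum() * (1.0 / d), wrapped)


def vicreg_loss(Za, Zb, weights: LossWeights = LossWeights(),
                invariance_scale: str = "per_sample"):
    """Weighted variance/invariance/covariance objective.

    Returns ``(total, components)`` where ``components`` holds the three
    unweighted terms: ``s`` (invariance), ``v`` (variance, summed over the
    two batches) and ``c`` (covariance, summed over the two batches).

    ``invariance_scale`` selects the normalisation of the invariance term:
    ``"per_sample"`` (the default) averages squared pair distances over the
    batch only, so the term grows linearly with the embedding dimension d;
    ``"per_element"`` additionally divides by d (mean-squared-error
    semantics, the convention of the joint-embedding literature's reference
    pseudocode).  Per-sample scaling makes the collapse pressure of the
    invariance term scale with d, so training loops default to per-element.
    """
    weights.validate()
    if invariance_scale not in ("per_sample", "per_element"):
        raise ValueError("invariance_scale must be 'per_sample' or 'per_element'")
    Za_t, wa = _as_tensor(Za)
    Zb_t, wb = _as_tensor(Zb)
    _check_batch(Za_t, "Za")
    _check_batch(Zb_t, "Zb")
    if Za_t.shape != Zb_t.shape:
        raise ValueError("Za and Zb must have the same shape")
    keep = wa or wb
    s = invariance_term(Za_t, Zb_t)
    if invariance_scale == "per_element":
        s = s * (1.0 / Za_t.shape[1])
    v = variance_term(Za_t, weights.gamma, weights.eps) + variance_term(
        Zb_t, weights.gamma, weights.eps
    )
    c = covariance_term(Za_t) + covariance_term(Zb_t)
    total = weights.lam * s + weights.mu * v + weights.phi * c
    if keep:
        return total, {"s": s, "v": v, "c": c}
    return total.item(), {"s": s.item(), "v": v.item(), "c": c.item()}
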