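"""The two contrastive objectives against naive reference implementations,
closed-form identities, and finite-difference gradients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motionssl.autograd import Tensor
from motionssl.losses import (LossWeights, barlow_loss, covariance_term,
                              cross_correlation, invariance_term,
                              variance_term, vicreg_loss)

from conftest import numerical_gradient

# ---------------------------------------------------------------------------
# Naive reference implementations (double loops, no vectorisation): the
# independent oracles for the vectorised code paths.
# ---------------------------------------------------------------------------


def oracle_cross_correlation(za, zb, center=True):
    za = za.astype(float).copy()
    zb = zb.astype(float).copy()
    n, d = za.shape
    if center:
        for j in range(d):
            za[:, j] -= za[:, j].mean()
            zb[:, j] -= zb[:, j].mean()
    C = np.zeros((d, d))
    for i in range(d):
        for j in range(d):
            num = sum(za[b, i] * zb[b, j] for b in range(n))
            na = max(np.sqrt(sum(za[b, i] ** 2 for b in range(n))), 1e-12)
            nb = max(np.sqrt(sum(zb[b, j] ** 2 for b in range(n))), 1e-12)
            C[i, j] = num / (na * nb)
    return C


def oracle_barlow(C, beta):
    d = C.shape[0]
    on = sum((1.0 - C[i, i]) ** 2 for i in range(d))
    off = sum(C[i, j] ** 2 for i in range(d) for j in range(d) if i != j)
    return on + beta * off


def oracle_variance(Z, gamma=1.0, eps=1e-4):
    n, d = Z.shape
    total = 0.0
    for j in range(d):
        col = Z[:, j]
        var = sum((v - col.mean()) ** 2 for v in col) / (n - 1)
        total += max(0.0, gamma - np.sqrt(var + eps))
    return total / d


def oracle_invariance(Za, Zb):
    n = Za.shape[0]
    return sum(np.sum((Za[j] - Zb[j]) ** 2) for j in range(n)) / n


def oracle_covariance(Z):
    n, d = Z.shape
    mean = Z.mean(axis=0)
    C = np.zeros((d, d))
    for j in range(n):
        diff = (Z[j] - mean).reshape(-1, 1)
        C += diff @ diff.T
    C /= n - 1
    return sum(C[i, j] ** 2 for i in range(d) for j in range(d) if i != j) / d


# ---------------------------------------------------------------------------
# Closed-form identities
# ---------------------------------------------------------------------------


class TestClosedForms:
    def test_identity_correlation_has_zero_loss(self):
        assert barlow_loss(np.eye(5), beta=0.005) == pytest.approx(0.0, abs=1e-12)

    def test_zero_correlation_loss_counts_the_diagonal(self):
        assert barlow_loss(np.zeros((3, 3)), beta=7.0) == pytest.approx(3.0, abs=1e-12)

    def test_single_off_diagonal_entry(self):
        C = np.eye(3)
        C[0, 2] = 0.5
        assert barlow_loss(C, beta=0.005) == pytest.approx(0.005 * 0.25, abs=1e-12)

    def test_constant_batch_variance_hinge(self):
        Z = np.full((6, 4), 2.5)
        assert variance_term(Z, gamma=1.0, eps=1e-4) == pytest.approx(
            1.0 - np.sqrt(1e-4), abs=1e-12)

    def test_variance_inactive_when_spread_exceeds_gamma(self):
        Z = np.diag([10.0, -10.0, 10.0, -10.0])  # std per dim well above 1
        assert variance_term(Z) == 0.0

    def test_single_pair_invariance_is_squared_distance(self):
        assert invariance_term(np.zeros((1, 2)), np.array([[3.0, 4.0]])) == 25.0

    def test_identical_embeddings_have_zero_invariance(self):
        Z = np.random.default_rng(0).normal(size=(7, 3))
        assert invariance_term(Z, Z) == 0.0

    def test_covariance_of_one_dimension_is_zero(self):
        assert covariance_term(np.random.default_rng(1).normal(size=(9, 1))) == 0.0

    def test_covariance_of_orthogonal_centered_columns_is_zero(self):
        Z = np.array([[1.0, 1.0], [-1.0, 1.0], [1.0, -1.0], [-1.0, -1.0]])
        assert covariance_term(Z) == pytest.approx(0.0, abs=1e-12)

    def test_self_correlation_of_decorrelated_columns_is_identity(self):
        Z = np.array([[1.0, 1.0], [-1.0, 1.0], [1.0, -1.0], [-1.0, -1.0]])
        np.testing.assert_allclose(cross_correlation(Z, Z), np.eye(2), atol=1e-12)

    def test_sign_flip_gives_minus_one_diagonal(self):
        Z = np.random.default_rng(2).normal(size=(6, 4))
        C = cross_correlation(Z, -Z)
        np.testing.assert_allclose(np.diag(C), -1.0, atol=1e-10)

    def test_vicreg_vanishes_for_ideal_embeddings(self):
        Z = np.array([[2.0, 2.0], [-2.0, 2.0], [2.0, -2.0], [-2.0, -2.0]])
        total, comp = vicreg_loss(Z, Z.copy())
        assert total == pytest.approx(0.0, abs=1e-12)
        assert comp == {"s": 0.0, "v": 0.0, "c": 0.0}

    def test_weight_masking_reduces_to_invariance(self):
        rng = np.random.default_rng(3)
        Za, Zb = rng.normal(size=(6, 4)), rng.normal(size=(6, 4))
        w = LossWeights(lam=1.0, mu=0.0, phi=0.0)
        total, _ = vicreg_loss(Za, Zb, w)
        assert total == pytest.approx(invariance_term(Za, Zb), abs=1e-12)

    def test_per_element_scaling_divides_invariance_by_dimension(self):
        rng = np.random.default_rng(4)
        Za, Zb = rng.normal(size=(6, 4)), rng.normal(size=(6, 4))
        w = LossWeights(lam=1.0, mu=0.0, phi=0.0)
        total, comp = vicreg_loss(Za, Zb, w, invariance_scale="per_element")
        assert total == pytest.approx(invariance_term(Za, Zb) / 4, abs=1e-12)
        assert comp["s"] == pytest.approx(total, abs=1e-12)


# ---------------------------------------------------------------------------
# Oracle equivalence on random batches
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("seed", range(100))
def test_vectorised_losses_match_naive_oracles(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 17))
    d = int(rng.integers(1, 9))
    Za = rng.normal(size=(n, d))
    Zb = rng.normal(size=(n, d))
    if d >= 1:
        np.testing.assert_allclose(invariance_term(Za, Zb),
                                   oracle_invariance(Za, Zb), atol=1e-8)
        np.testing.assert_allclose(variance_term(Za), oracle_variance(Za), atol=1e-8)
        np.testing.assert_allclose(covariance_term(Za), oracle_covariance(Za),
                                   atol=1e-8)
        C = cross_correlation(Za, Zb)
        np.testing.assert_allclose(C, oracle_cross_correlation(Za, Zb), atol=1e-8)
        beta = 0.005
        np.testing.assert_allclose(barlow_loss(C, beta), oracle_barlow(C, beta),
                                   atol=1e-8)
        total, comp = vicreg_loss(Za, Zb)
        ref = (25.0 * oracle_invariance(Za, Zb)
               + 25.0 * (oracle_variance(Za) + oracle_variance(Zb))
               + 1.0 * (oracle_covariance(Za) + oracle_covariance(Zb)))
        np.testing.assert_allclose(total, ref, atol=1e-8)


def test_duplicated_column_covariance_matches_explicit_computation():
    rng = np.random.default_rng(9)
    col = rng.normal(size=8)
    Z = np.stack([col, col], axis=1)
    np.testing.assert_allclose(covariance_term(Z), oracle_covariance(Z), atol=1e-12)


# ---------------------------------------------------------------------------
# Gradients
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("seed", range(10))
def test_barlow_objective_gradient_matches_finite_differences(seed):
    rng = np.random.default_rng(100 + seed)
    Za0 = rng.normal(size=(6, 4))
    Zb = rng.normal(size=(6, 4))

    def f(v):
        return barlow_loss(cross_correlation(v, Zb), 0.005)

    Za = Tensor(Za0, requires_grad=True)
    barlow_loss(cross_correlation(Za, Tensor(Zb)), 0.005).backward()
    num = numerical_gradient(f, Za0)
    denom = max(np.linalg.norm(num), 1e-8)
    assert np.linalg.norm(Za.grad - num) / denom < 1e-4


@pytest.mark.parametrize("seed", range(10))
def test_vicreg_objective_gradient_matches_finite_differences(seed):
    rng = np.random.default_rng(200 + seed)
    Za0 = rng.normal(size=(6, 4))
    Zb = rng.normal(size=(6, 4))
    w = LossWeights()

    def f(v):
        return vicreg_loss(v, Zb, w)[0]

    Za = Tensor(Za0, requires_grad=True)
    total, _ = vicreg_loss(Za, Tensor(Zb), w)
    total.backward()
    num = numerical_gradient(f, Za0)
    denom = max(np.linalg.norm(num), 1e-8)
    assert np.linalg.norm(Za.grad - num) / denom < 1e-4


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_losses_nonnegative_and_row_permutation_invariant(seed):
    rng = np.random.default_rng(seed)
    n, d = int(rng.integers(3, 10)), int(rng.integers(2, 6))
    Za, Zb = rng.normal(size=(n, d)), rng.normal(size=(n, d))
    perm = rng.permutation(n)
    total, comp = vicreg_loss(Za, Zb)
    total_p, _ = vicreg_loss(Za[perm], Zb[perm])
    assert total >= 0 and all(v >= 0 for v in comp.values())
    assert total_p == pytest.approx(total, rel=1e-10)
    bl = barlow_loss(cross_correlation(Za, Zb))
    bl_p = barlow_loss(cross_correlation(Za[perm], Zb[perm]))
    assert bl >= 0
    assert bl_p == pytest.approx(bl, rel=1e-10)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_self_correlation_has_unit_diagonal(seed):
    rng = np.random.default_rng(seed)
    Z = rng.normal(size=(int(rng.integers(3, 12)), int(rng.integers(1, 7))))
    np.testing.assert_allclose(np.diag(cross_correlation(Z, Z)), 1.0, atol=1e-10)


def test_invariance_decreases_monotonically_under_interpolation():
    rng = np.random.default_rng(11)
    Za = rng.normal(size=(8, 5))
    Zb = rng.normal(size=(8, 5))
    values = [invariance_term(Za, Zb + t * (Za - Zb)) for t in np.linspace(0, 1, 9)]
    assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))


def test_error_contracts():
    Z = np.zeros((1, 3))
    with pytest.raises(ValueError, match="at least 2"):
        variance_term(np.zeros((1, 3)))
    with pytest.raises(ValueError, match="at least 2"):
        cross_correlation(Z, Z)
    with pytest.raises(ValueError, match="square"):
        barlow_loss(np.zeros((2, 3)))
    with pytest.raises(ValueError, match="same shape"):
        invariance_term(np.zeros((3, 2)), np.zeros((3, 4)))
    with pytest.raises(ValueError, match="collapse"):
        cross_correlation(np.zeros((4, 2)), np.ones((4, 2)), strict=True)
    # non-strict call floors the norms instead of raising
    C = cross_correlation(np.zeros((4, 2)), np.ones((4, 2)))
    assert np.isfinite(C).all()
    with pytest.raises(ValueError, match="invariance_scale"):
        vicreg_loss(np.zeros((3, 2)), np.zeros((3, 2)), invariance_scale="bogus")
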