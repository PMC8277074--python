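"""Loss terms against independent loop/quadrature oracles and their
analytic properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from moesimvae import (LossBreakdown, depict_loss, depict_targets, kl_loss,
                       reconstruction_loss, similarity_loss, total_loss)
from moesimvae._autodiff import Tensor

EPS = 1e-7


# ---------------------------------------------------------------- oracles

def bce_loop(x, xr):
    xr = np.clip(xr, EPS, 1 - EPS)
    n, d = x.shape
    total = 0.0
    for i in range(n):
        for j in range(d):
            total -= x[i, j] * np.log(xr[i, j]) + (1 - x[i, j]) * np.log(1 - xr[i, j])
    return total / n


def similarity_loop(p, S):
    n = p.shape[0]
    g = np.clip(p @ p.T, EPS, 1 - EPS)
    total = 0.0
    for i in range(n):
        for j in range(n):
            total -= S[i, j] * np.log(g[i, j]) + (1 - S[i, j]) * np.log(1 - g[i, j])
    return total / n**2


def depict_loop(p, p_noisy):
    n, k = p.shape
    col = p.sum(axis=0)
    q = np.zeros_like(p)
    for i in range(n):
        denom = sum(p[i, kk] / np.sqrt(col[kk]) for kk in range(k))
        for kk in range(k):
            q[i, kk] = (p[i, kk] / np.sqrt(col[kk])) / denom
    total = 0.0
    for i in range(n):
        for kk in range(k):
            total -= q[i, kk] * np.log(np.clip(p_noisy[i, kk], EPS, 1 - EPS))
    return total / n


def kl_gauss_quadrature(sigmas):
    """KL(N(0,I) || N(0,diag(sigmas))) by 1-D numerical integration."""
    total = 0.0
    for s2 in sigmas:
        f = lambda t: norm.pdf(t) * (norm.logpdf(t) - norm.logpdf(t, scale=np.sqrt(s2)))
        total += quad(f, -12, 12)[0]
    return total


# ----------------------------------------------------------------- KL term

class TestKLLoss:
    def test_unit_variance_gives_zero(self):
        # two clusters whose per-dimension ML variance is exactly 1
        z = np.array([[-1.0, 1.0], [1.0, -1.0],
                      [4.0, 6.0], [6.0, 4.0]])
        hard = np.array([0, 0, 1, 1])
        assert abs(kl_loss(z, hard=hard).item()) < 1e-9

    def test_closed_form_single_dim(self):
        # one cluster, D_z=1, variance exactly 2
        z = np.array([[-np.sqrt(2.0)], [np.sqrt(2.0)]])
        expected = 0.5 * (1 / 2 - 1 + np.log(2))
        assert abs(kl_loss(z, hard=np.array([0, 0])).item() - expected) < 1e-12

    @pytest.mark.parametrize("d_z", [1, 2, 3])
    def test_matches_quadrature_oracle(self, d_z, rng):
        z = rng.standard_normal((40, d_z)) * rng.uniform(0.5, 2.0, size=d_z)
        hard = np.zeros(40, dtype=int)
        sigmas = z.var(axis=0)  # same ML estimate the loss uses
        assert abs(kl_loss(z, hard=hard).item() - kl_gauss_quadrature(sigmas)) < 1e-3

    def test_mean_over_clusters_and_small_clusters_skipped(self, rng):
        z = rng.standard_normal((21, 2))
        hard = np.array([0] * 10 + [1] * 10 + [2])  # cluster 2 has 1 member
        per = [kl_gauss_quadrature(z[hard == k].var(axis=0)) for k in (0, 1)]
        assert abs(kl_loss(z, hard=hard).item() - np.mean(per)) < 1e-3

    def test_nonnegative_for_random_inputs(self, rng):
        for _ in range(20):
            z = rng.standard_normal((30, 3)) * rng.uniform(0.1, 3.0)
            hard = rng.integers(0, 3, 30)
            assert kl_loss(z, hard=hard).item() >= -1e-9

    def test_global_variance_option(self, rng):
        z = rng.standard_normal((30, 2)) * 1.7
        hard = rng.integers(0, 3, 30)
        global_val = kl_loss(z, hard=hard, per_cluster=False).item()
        assert abs(global_val - kl_gauss_quadrature(z.var(axis=0))) < 1e-3
        assert global_val != kl_loss(z, hard=hard).item()

    def test_gradient_flows_to_latent(self, rng):
        z = Tensor(rng.standard_normal((10, 2)), requires_grad=True)
        kl_loss(z, hard=np.zeros(10, dtype=int)).backward()
        assert z.grad is not None and np.abs(z.grad).sum() > 0


# -------------------------------------------------------- reconstruction

class TestReconstructionLoss:
    def test_perfect_binary_reconstruction_near_zero(self, rng):
        x = (rng.random((6, 5)) > 0.5).astype(float)
        assert reconstruction_loss(x, x).item() < 1e-5

    def test_fair_coin_entropy(self):
        x = np.full((4, 3), 0.5)
        assert np.isclose(reconstruction_loss(x, x).item(), 3 * np.log(2))

    def test_matches_loop_oracle(self, rng):
        x = rng.random((12, 7))
        xr = rng.uniform(0.05, 0.95, (12, 7))
        assert abs(reconstruction_loss(x, xr).item() - bce_loop(x, xr)) < 1e-8

    def test_truncated_form_drops_complement(self, rng):
        x = rng.random((5, 4))
        xr = rng.uniform(0.1, 0.9, (5, 4))
        expected = np.sum(x * np.log(xr)) / 5
        assert np.isclose(reconstruction_loss(x, xr, truncated=True).item(), expected)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            reconstruction_loss(rng.random((3, 2)), rng.random((2, 3)))


# ------------------------------------------------------------- similarity

class TestSimilarityLoss:
    def test_exact_block_factorization_near_zero(self):
        p = np.repeat(np.eye(2), 3, axis=0)  # 6 samples, 2 one-hot blocks
        S = (p @ p.T)
        assert similarity_loss(p, S).item() < 1e-5

    def test_identity_case(self):
        p = np.eye(2)
        assert similarity_loss(p, np.eye(2)).item() < 1e-5

    def test_matches_loop_oracle(self, rng):
        p = rng.dirichlet(np.ones(4), 10)
        S = (rng.random((10, 10)) > 0.5).astype(float)
        S = np.triu(S) + np.triu(S, 1).T
        np.fill_diagonal(S, 1.0)
        assert abs(similarity_loss(p, S).item() - similarity_loop(p, S)) < 1e-8

    def test_asymmetric_S_rejected(self, rng):
        p = rng.dirichlet(np.ones(2), 3)
        S = np.array([[1.0, 1, 0], [0, 1, 0], [0, 0, 1]])
        with pytest.raises(ValueError, match="symmetric"):
            similarity_loss(p, S)

    def test_decreases_toward_exact_factorization(self, rng):
        """Interpolating random P toward the exact block factorization of
        a block-diagonal S lowers the loss monotonically (a fully random
        start may show one small initial bump before the decrease)."""
        target = np.repeat(np.eye(3), 4, axis=0)
        S = target @ target.T
        p0 = rng.dirichlet(np.ones(3), 12)
        losses = []
        for t in np.linspace(0, 1, 8):
            p = (1 - t) * p0 + t * target
            losses.append(similarity_loss(p, S).item())
        assert all(a >= b - 1e-12 for a, b in zip(losses[1:], losses[2:]))
        assert losses[-1] < losses[0]
        assert losses[-1] < 1e-5


# ------------------------------------------------------------------ DEPICT

class TestDepictLoss:
    def test_uniform_symmetry(self):
        n, k = 8, 4
        p = np.full((n, k), 1 / k)
        q = depict_targets(p)
        assert np.allclose(q, 1 / k)
        assert np.isclose(depict_loss(p, p).item(), np.log(k))

    def test_hand_case_matches_loop(self):
        p = np.array([[0.9, 0.1], [0.1, 0.9]])
        p_noisy = np.array([[0.8, 0.2], [0.3, 0.7]])
        assert abs(depict_loss(p, p_noisy).item() - depict_loop(p, p_noisy)) < 1e-8

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_target_rows_sum_to_one(self, seed):
        r = np.random.default_rng(seed)
        p = r.dirichlet(np.full(r.integers(2, 6), 0.5), r.integers(2, 30))
        assert np.allclose(depict_targets(p).sum(axis=1), 1.0, atol=1e-8)

    def test_minimized_at_noisy_equals_target(self, rng):
        p = rng.dirichlet(np.ones(3), 15)
        q = depict_targets(p)
        at_q = depict_loss(p, q).item()
        for _ in range(10):
            other = rng.dirichlet(np.ones(3), 15)
            assert depict_loss(p, other).item() >= at_q - 1e-10

    def test_zero_column_skipped(self):
        p = np.array([[1.0, 0.0], [1.0, 0.0]])
        val = depict_loss(p, p).item()
        assert np.isfinite(val) and val < 1e-5


# ------------------------------------------------------------- combination

class TestTotalLoss:
    def test_identities_hold(self, rng):
        r, k, s, d = rng.random(4)
        b = total_loss(r, k, s, d, pi1=0.1, pi2=1.0)
        assert np.isclose(b.vae, b.reconst + 0.1 * b.kl, atol=1e-8)
        assert np.isclose(b.clustering, b.similarity + 1.0 * b.depict, atol=1e-8)
        assert np.isclose(b.total, b.vae + b.clustering, atol=1e-8)

    def test_zero_weights_reduce_to_reconst_plus_similarity(self):
        b = total_loss(2.0, 5.0, 3.0, 7.0, pi1=0.0, pi2=0.0)
        assert b.total == 5.0

    def test_all_zero_components(self):
        assert total_loss(0, 0, 0, 0, 1.0, 1.0).total == 0.0

    def test_nan_component_named(self):
        with pytest.raises(FloatingPointError, match="depict"):
            total_loss(1.0, 1.0, 1.0, np.nan, 0.1, 1.0)

    def test_breakdown_is_dataclass_of_floats(self):
        b = total_loss(1, 2, 3, 4, 0.5, 0.5)
        assert isinstance(b, LossBreakdown)
        assert all(isinstance(v, float) for v in vars(b).values())
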