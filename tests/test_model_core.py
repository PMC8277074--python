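"""Contracts of the encoder, gating network and expert routing."""

import numpy as np
import pytest

from moesimvae import ModelConfig, MoESimVAE, cluster_means
from moesimvae._autodiff import Tensor


@pytest.fixture()
def cfg():
    return ModelConfig(n_experts=3, latent_dim=2, input_dim=20, seed=42)


@pytest.fixture()
def model(cfg):
    return MoESimVAE(cfg)


class TestEncode:
    def test_shape_contract(self, model, rng):
        x = rng.random((8, 20))
        lat = model.encode(x)
        assert lat.mean.shape == lat.log_var.shape == lat.z.shape == (8, 2)

    def test_same_seed_identical_sample(self, model, rng):
        x = rng.random((8, 20))
        z1 = model.encode(x).z
        z2 = model.encode(x).z  # fresh default generator each call
        assert np.array_equal(z1, z2)

    def test_zero_variance_limit_returns_mean(self, rng):
        cfg = ModelConfig(n_experts=3, latent_dim=2, input_dim=20,
                          posterior_logvar=-1e6, seed=0)
        model = MoESimVAE(cfg)
        x = rng.random((5, 20))
        lat = model.encode(x)
        assert np.array_equal(lat.z, lat.mean)

    def test_dimension_mismatch_raises(self, model, rng):
        with pytest.raises(ValueError, match="expected"):
            model.encode(rng.random((4, 7)))

    def test_nonfinite_input_raises(self, model):
        x = np.full((3, 20), np.nan)
        with pytest.raises(ValueError, match="finite|0, 1"):
            model.encode(x)


class TestGate:
    def test_rows_stochastic_and_hard_is_argmax(self, model, rng):
        z = rng.standard_normal((50, 2)) * 3
        a = model.gate(z)
        assert np.allclose(a.p.sum(axis=1), 1.0, atol=1e-6)
        assert a.p.min() >= 0 and a.p.max() <= 1
        assert np.array_equal(a.hard, a.p.argmax(axis=1))

    def test_tie_breaks_to_lowest_index(self, cfg, rng):
        model = MoESimVAE(cfg)
        for layer in model.gating.layers:  # zero net -> uniform p, all tied
            layer.W.data[:] = 0.0
            layer.b.data[:] = 0.0
        a = model.gate(rng.standard_normal((10, 2)))
        assert np.allclose(a.p, 1.0 / cfg.n_experts)
        assert np.array_equal(a.hard, np.zeros(10, dtype=int))

    def test_dropout_zero_gives_identical_noisy_path(self, rng):
        cfg = ModelConfig(n_experts=3, latent_dim=2, input_dim=20,
                          dropout_rate=0.0, seed=1)
        a = MoESimVAE(cfg).gate(rng.standard_normal((6, 2)))
        assert np.array_equal(a.p, a.p_noisy)

    def test_dropout_perturbs_noisy_path(self, model, rng):
        a = model.gate(rng.standard_normal((40, 2)))
        assert not np.array_equal(a.p, a.p_noisy)
        assert np.allclose(a.p_noisy.sum(axis=1), 1.0, atol=1e-6)


class TestDecodeMoE:
    def test_output_range_and_shape(self, model, rng):
        z = rng.standard_normal((9, 2))
        hard = rng.integers(0, 3, 9)
        out = model.decode_moe(z, hard)
        assert out.shape == (9, 20)
        assert out.min() > 0 and out.max() < 1

    def test_single_sample_routing_matches_expert_alone(self, model, rng):
        z = rng.standard_normal((1, 2))
        out = model.decode_moe(z, np.array([2]))
        direct = model.experts[2](Tensor(z)).sigmoid().data
        assert np.array_equal(out, direct)

    def test_permuting_rows_permutes_output(self, model, rng):
        z = rng.standard_normal((7, 2))
        hard = rng.integers(0, 3, 7)
        perm = rng.permutation(7)
        out = model.decode_moe(z, hard)
        out_perm = model.decode_moe(z[perm], hard[perm])
        assert np.allclose(out_perm, out[perm])

    def test_index_out_of_range_raises(self, model, rng):
        with pytest.raises(IndexError):
            model.decode_moe(rng.standard_normal((2, 2)), np.array([0, 3]))

    def test_unselected_experts_get_no_gradient(self, model, rng):
        z = Tensor(rng.standard_normal((6, 2)), requires_grad=True)
        out = model.decode_t(z, np.zeros(6, dtype=int))
        out.sum().backward()
        assert all(p.grad is not None for p in model.experts[0].parameters)
        for k in (1, 2):
            assert all(p.grad is None for p in model.experts[k].parameters)

    def test_zeroing_expert_changes_only_its_rows(self, cfg, rng):
        model = MoESimVAE(cfg)
        z = rng.standard_normal((12, 2))
        hard = np.array([0, 1, 2] * 4)
        before = model.decode_moe(z, hard)
        for p in model.experts[1].parameters:
            p.data[:] = 0.0
        after = model.decode_moe(z, hard)
        changed = ~np.all(np.isclose(before, after), axis=1)
        assert np.array_equal(changed, hard == 1)


class TestClusterMeans:
    def test_single_cluster_equals_column_mean(self, rng):
        z = rng.standard_normal((20, 3))
        st = cluster_means(z, np.ones((20, 1)))
        assert np.allclose(st.mu[0], z.mean(axis=0))
        assert st.omega[0] == 1.0

    def test_hard_one_hot_case(self):
        z = np.array([[0.0, 0.0], [2.0, 2.0]])
        p = np.eye(2)
        st = cluster_means(z, p)
        assert np.allclose(st.mu, z)
        assert np.array_equal(st.n_k, [1, 1])
        assert np.allclose(st.omega, [0.5, 0.5])

    def test_matches_double_loop_oracle(self, rng):
        n, k, d = 50, 4, 3
        z = rng.standard_normal((n, d))
        p = rng.dirichlet(np.ones(k), n)
        st = cluster_means(z, p)
        hard = p.argmax(axis=1)
        for kk in range(k):
            n_k = int((hard == kk).sum())
            expected = sum(p[i, kk] * z[i] for i in range(n)) / n_k
            assert np.allclose(st.mu[kk], expected, atol=1e-10)

    def test_empty_cluster_flagged(self):
        z = np.zeros((3, 2))
        p = np.tile([1.0, 0.0], (3, 1))
        st = cluster_means(z, p)
        assert st.empty[1] and not st.empty[0]
        assert np.isnan(st.mu[1]).all()
        assert st.omega.sum() == 1.0

    def test_soft_variant_is_weighted_mean(self, rng):
        z = rng.standard_normal((30, 2))
        p = rng.dirichlet(np.ones(3), 30)
        st = cluster_means(z, p, soft=True)
        expected = (p.T @ z) / p.sum(axis=0)[:, None]
        assert np.allclose(st.mu, expected)


class TestCheckpoint:
    def test_roundtrip_preserves_behavior(self, model, rng, tmp_path):
        x = rng.random((5, 20))
        model.scaling_meta = {"mins": [0.0] * 20, "ranges": [1.0] * 20}
        path = tmp_path / "model.ckpt"
        model.save(path)
        loaded = MoESimVAE.load(path)
        assert np.array_equal(loaded.predict_proba(x), model.predict_proba(x))
        assert loaded.cfg == model.cfg
        assert loaded.scaling_meta == model.scaling_meta
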