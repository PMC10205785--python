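"""Graph attention autoencoder: attention algebra, forward passes,
hand-checked gradients, training behavior."""

import numpy as np
import pytest
from sklearn.metrics import silhouette_score

from adept.gae import (
    Embedding,
    GAEConfig,
    GAEParams,
    _Layer,
    _loss_and_grads,
    attention_coefficients,
    decode,
    encode,
    init_params,
    train_gae,
)
from adept.graph import SpatialGraph, build_knn_graph


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def two_node_graph():
    edges = [(0, 0), (0, 1), (1, 0), (1, 1)]
    return SpatialGraph(n_nodes=2, edges=np.array(edges), k=1)


class TestAttentionCoefficients:
    def test_singleton_neighborhood(self):
        g = SpatialGraph(n_nodes=1, edges=np.array([[0, 0]]), k=0)
        alpha = attention_coefficients(np.array([[3.0]]), np.eye(1), np.ones(2), g)
        np.testing.assert_allclose(alpha, [1.0])

    def test_identical_features_uniform(self):
        g = build_knn_graph(np.arange(10, dtype=float).reshape(-1, 1).repeat(2, 1), k=3)
        h = np.ones((10, 4))
        rng = np.random.default_rng(0)
        alpha = attention_coefficients(h, rng.random((3, 4)), rng.random(6), g)
        for u in range(10):
            mask = g.edges[:, 0] == u
            np.testing.assert_allclose(alpha[mask], 1.0 / mask.sum())

    def test_two_node_hand_computation(self):
        # h = [1, 2], W = [1], a = [1, 1]: pairwise scores for node 0 are
        # sigmoid(1+1) and sigmoid(1+2); softmax over exp of those
        g = two_node_graph()
        alpha = attention_coefficients(
            np.array([[1.0], [2.0]]), np.array([[1.0]]), np.array([1.0, 1.0]), g
        )
        e2, e3 = np.exp(sigmoid(2.0)), np.exp(sigmoid(3.0))
        e4 = np.exp(sigmoid(4.0))
        # edges sorted: (0,0) (0,1) (1,0) (1,1)
        np.testing.assert_allclose(
            alpha, [e2 / (e2 + e3), e3 / (e2 + e3), e3 / (e3 + e4), e4 / (e3 + e4)]
        )

    def test_rows_sum_to_one(self, small_graph):
        _, g = small_graph
        rng = np.random.default_rng(1)
        alpha = attention_coefficients(rng.random((30, 5)), rng.random((4, 5)), rng.random(8), g)
        rows = np.bincount(g.edges[:, 0], weights=alpha, minlength=30)
        np.testing.assert_allclose(rows, 1.0, atol=1e-12)


class TestEncodeDecode:
    def test_zero_input_zero_embedding(self):
        g = two_node_graph()
        cfg = GAEConfig(layer_dims=[3, 4, 2], seed=0)
        params = init_params(cfg)
        H = encode(np.zeros((2, 3)), g, params)
        np.testing.assert_allclose(H, 0.0, atol=1e-15)

    def test_single_node_identity_weights(self):
        g = SpatialGraph(n_nodes=1, edges=np.array([[0, 0]]), k=0)
        lay = _Layer(W=np.eye(2), b=np.zeros(2), a=np.array([1.0, 1, 1, 1]))
        params = GAEParams(encoder=[lay], decoder=[])
        h0 = np.array([[0.5, -0.7]])
        expected = np.where(h0 > 0, h0, np.expm1(h0))
        np.testing.assert_allclose(encode(h0, g, params), expected)

    def test_two_node_hand_computed_layer(self):
        g = two_node_graph()
        lay = _Layer(W=np.array([[1.0]]), b=np.zeros(1), a=np.array([1.0, 1.0]))
        params = GAEParams(encoder=[lay], decoder=[])
        h0 = np.array([[1.0], [2.0]])
        e2, e3, e4 = np.exp(sigmoid(2.0)), np.exp(sigmoid(3.0)), np.exp(sigmoid(4.0))
        a00, a01 = e2 / (e2 + e3), e3 / (e2 + e3)
        a10, a11 = e3 / (e3 + e4), e4 / (e3 + e4)
        expected = np.array([[a00 * 1 + a01 * 2], [a10 * 1 + a11 * 2]])  # ELU is id >0
        np.testing.assert_allclose(encode(h0, g, params), expected)

    def test_decoder_mirrors_encoder_dims(self):
        cfg = GAEConfig(layer_dims=[7, 5, 3], seed=0)
        params = init_params(cfg)
        g = build_knn_graph(np.random.default_rng(0).random((8, 2)), k=2)
        X = np.random.default_rng(1).random((8, 7))
        H = encode(X, g, params)
        assert H.shape == (8, 3)
        Xhat = decode(H, g, params)
        assert Xhat.shape == X.shape

    def test_checkpoint_roundtrip(self, tmp_path):
        cfg = GAEConfig(layer_dims=[4, 3, 2], seed=5)
        params = init_params(cfg)
        params.save(tmp_path / "ckpt.npz")
        loaded = GAEParams.load(tmp_path / "ckpt.npz")
        for a, b in zip(params.all_arrays(), loaded.all_arrays()):
            np.testing.assert_array_equal(a, b)


class TestGradients:
    def test_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        n, g_dim = 12, 7
        X = rng.random((n, g_dim))
        graph = build_knn_graph(rng.random((n, 2)), k=3)
        cfg = GAEConfig(layer_dims=[g_dim, 5, 3], seed=1)
        params = init_params(cfg)
        _, grads, _ = _loss_and_grads(X, params, graph)
        eps = 1e-5
        for arr, grad in zip(params.all_arrays(), grads):
            flat = arr.reshape(-1)
            gflat = grad.reshape(-1)
            for idx in range(0, flat.size, max(1, flat.size // 10)):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _, _ = _loss_and_grads(X, params, graph)
                flat[idx] = orig - eps
                lm, _, _ = _loss_and_grads(X, params, graph)
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert gflat[idx] == pytest.approx(num, rel=1e-4, abs=1e-7)


class TestTraining:
    def make_rank1(self):
        rng = np.random.default_rng(2)
        u = rng.random(50)
        v = rng.random(20)
        X = np.outer(u, v)
        graph = build_knn_graph(rng.random((50, 2)), k=4)
        return X, graph

    def test_loss_decreases_on_learnable_signal(self):
        X, graph = self.make_rank1()
        cfg = GAEConfig(layer_dims=[20, 8, 4], iterations=100, seed=0)
        _, emb = train_gae(X, graph, cfg)
        assert emb.loss_history[-1] < emb.loss_history[0]
        assert len(emb.loss_history) == 100

    def test_seeded_determinism_bit_identical(self):
        X, graph = self.make_rank1()
        cfg = GAEConfig(layer_dims=[20, 8, 4], iterations=30, seed=9)
        _, emb1 = train_gae(X, graph, cfg)
        _, emb2 = train_gae(X, graph, cfg)
        assert emb1.loss_history == emb2.loss_history
        np.testing.assert_array_equal(emb1.H, emb2.H)

    def test_attention_rows_sum_to_one_throughout(self):
        X, graph = self.make_rank1()
        cfg = GAEConfig(
            layer_dims=[20, 8, 4], iterations=50, seed=3, track_attention=True
        )
        _, emb = train_gae(X, graph, cfg)
        assert emb.attention_deviation is not None
        assert emb.attention_deviation < 1e-6

    def test_block_copies_get_identical_embeddings(self):
        # 3 blocks of exact copies, within-block complete graph: embeddings
        # must coincide within blocks (permutation equivariance)
        rng = np.random.default_rng(4)
        protos = rng.random((3, 6))
        X = np.repeat(protos, 4, axis=0)
        edges = [
            (u, v)
            for b in range(3)
            for u in range(b * 4, b * 4 + 4)
            for v in range(b * 4, b * 4 + 4)
        ]
        graph = SpatialGraph(n_nodes=12, edges=np.array(edges), k=3)
        cfg = GAEConfig(layer_dims=[6, 4, 2], iterations=40, seed=0)
        _, emb = train_gae(X, graph, cfg)
        for b in range(3):
            block = emb.H[b * 4 : b * 4 + 4]
            np.testing.assert_allclose(block - block[0], 0.0, atol=1e-10)

    def test_embedding_separates_domains_better_than_raw(self, layered_normalized):
        norm, truth = layered_normalized
        graph = build_knn_graph(
            np.array([[int(p) for p in s.split("_")[1:]] for s in norm.spot_ids], float),
            k=6,
        )
        cfg = GAEConfig(layer_dims=[norm.n_genes, 64, 32], iterations=150, seed=0)
        _, emb = train_gae(norm.values, graph, cfg)
        sil_embed = silhouette_score(emb.H, truth.labels)
        sil_raw = silhouette_score(norm.values, truth.labels)
        assert sil_embed > sil_raw

    def test_width_mismatch_is_error(self):
        X, graph = self.make_rank1()
        cfg = GAEConfig(layer_dims=[19, 8, 4], iterations=5, seed=0)
        with pytest.raises(ValueError):
            train_gae(X, graph, cfg)
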