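"""GCN and attention layers: dense oracles, permutation properties,
shape contracts and gradient flow."""

import numpy as np
import pytest

from dialograph._autodiff import Tensor
from dialograph.nn import (AttentionReadout, GraphClassifier, GraphData,
                           InterViewAttentionMean, ModelConfig,
                           MultiHeadAttention, NodeEncoder, build_classifier,
                           classify, gcn_forward, normalized_adjacency)
from dialograph.training import class_weights, prepare_datasets, weighted_bce


def dense_attention_oracle(x, mha):
    """Independent numpy recomputation of multi-head attention."""
    wq, wk, wv, wo = (m.w.data for m in (mha.wq, mha.wk, mha.wv, mha.wo))
    bq, bk, bv, bo = (m.b.data for m in (mha.wq, mha.wk, mha.wv, mha.wo))
    n, d = x.shape
    h, dk = mha.n_heads, mha.d_head
    q = (x @ wq + bq).reshape(n, h, dk).transpose(1, 0, 2)
    k = (x @ wk + bk).reshape(n, h, dk).transpose(1, 0, 2)
    v = (x @ wv + bv).reshape(n, h, dk).transpose(1, 0, 2)
    out = np.zeros((h, n, dk))
    for head in range(h):
        scores = q[head] @ k[head].T / np.sqrt(dk)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        attn = e / e.sum(axis=1, keepdims=True)
        out[head] = attn @ v[head]
    return out.transpose(1, 0, 2).reshape(n, d) @ wo + bo


class TestGCN:
    def test_single_node_closed_form(self):
        # one node, no edges: Ahat = [[1]]; identity weights -> relu(x)
        x = np.array([[-1.0, 2.0]])
        out = gcn_forward(np.zeros((1, 1)), x, [np.eye(2)])
        assert np.array_equal(out, np.array([[0.0, 2.0]]))

    def test_matches_dense_recomputation(self):
        rng = np.random.default_rng(0)
        adj = np.abs(rng.standard_normal((5, 5)))
        adj = (adj + adj.T) / 2
        np.fill_diagonal(adj, 0)
        x = rng.standard_normal((5, 3))
        w = rng.standard_normal((3, 4))
        out = gcn_forward(adj, x, [w])
        a = adj + np.eye(5)
        d = np.diag(1.0 / np.sqrt(a.sum(axis=1)))
        expected = np.maximum(d @ a @ d @ x @ w, 0)
        assert np.allclose(out, expected, atol=1e-6)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        adj = np.abs(rng.standard_normal((7, 7)))
        adj = (adj + adj.T) / 2
        x = rng.standard_normal((7, 4))
        w = [rng.standard_normal((4, 4)), rng.standard_normal((4, 4))]
        perm = rng.permutation(7)
        out = gcn_forward(adj, x, w)
        out_p = gcn_forward(adj[np.ix_(perm, perm)], x[perm], w)
        assert np.allclose(out[perm], out_p, atol=1e-10)

    def test_normalized_adjacency_symmetric(self):
        rng = np.random.default_rng(2)
        adj = np.abs(rng.standard_normal((6, 6)))
        adj = (adj + adj.T) / 2
        ahat = normalized_adjacency(adj)
        assert np.allclose(ahat, ahat.T)


class TestAttention:
    def test_readout_matches_dense_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((4, 8))
        ro = AttentionReadout(8, 2, np.random.default_rng(0))
        got = ro(Tensor(x)).data
        expected = dense_attention_oracle(x, ro.attn).mean(axis=0, keepdims=True)
        assert np.allclose(got, expected, atol=1e-6)

    def test_readout_permutation_invariant(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((6, 8))
        ro = AttentionReadout(8, 4, np.random.default_rng(1))
        perm = rng.permutation(6)
        assert np.allclose(ro(Tensor(x)).data, ro(Tensor(x[perm])).data, atol=1e-12)

    def test_single_node_readout_is_fixed_transform(self):
        x = np.random.default_rng(5).standard_normal((1, 8))
        ro = AttentionReadout(8, 2, np.random.default_rng(2))
        # softmax over one key is 1: readout = Wo(Wv x) on that node
        mha = ro.attn
        v = x @ mha.wv.w.data + mha.wv.b.data
        expected = v @ mha.wo.w.data + mha.wo.b.data
        assert np.allclose(ro(Tensor(x)).data, expected, atol=1e-9)


class TestNodeEncoder:
    def test_singleton_locality(self):
        enc = NodeEncoder(8, 2, np.random.default_rng(0))
        a = np.random.default_rng(1).standard_normal((1, 8))
        out1 = enc(a)
        out2 = enc(np.vstack([a]))  # same singleton again
        assert np.array_equal(out1.data, out2.data)

    def test_permutation_invariance(self):
        enc = NodeEncoder(8, 4, np.random.default_rng(0))
        s = np.random.default_rng(2).standard_normal((5, 8))
        perm = np.random.default_rng(3).permutation(5)
        assert np.allclose(enc(s).data, enc(s[perm]).data, atol=1e-12)

    def test_duplicated_singleton_equals_singleton(self):
        enc = NodeEncoder(8, 2, np.random.default_rng(0))
        a = np.random.default_rng(4).standard_normal((1, 8))
        dup = np.vstack([a, a])
        assert np.allclose(enc(a).data, enc(dup).data, atol=1e-9)

    def test_empty_set_rejected(self):
        enc = NodeEncoder(8, 2, np.random.default_rng(0))
        with pytest.raises(ValueError):
            enc(np.zeros((0, 8)))


class TestFusion:
    def test_symmetric_views_with_shared_weights(self):
        fusion = InterViewAttentionMean(8, 2, np.random.default_rng(0))
        # tie the two directions' weights
        fusion.enc_p = fusion.enc_t
        fusion.cross_p = fusion.cross_t
        x = Tensor(np.random.default_rng(1).standard_normal((3, 8)))
        out = fusion(x, x)
        st = fusion.cross_t(fusion.enc_t(x, x, x), fusion.enc_t(x, x, x),
                            fusion.enc_t(x, x, x)).mean(axis=0, keepdims=True)
        assert np.allclose(out.data, st.data, atol=1e-9)

    def test_empty_view_degrades_to_half_paths(self):
        fusion = InterViewAttentionMean(8, 2, np.random.default_rng(0))
        xt = Tensor(np.random.default_rng(2).standard_normal((4, 8)))
        out = fusion(xt, None)
        # hand-traced: patient side is a zero row; both summaries still defined
        zero = Tensor(np.zeros((1, 8)))
        ht = fusion.enc_t(xt, xt, xt)
        st = fusion.cross_t(ht, zero, zero).mean(axis=0, keepdims=True)
        sp = fusion.cross_p(zero, ht, ht).mean(axis=0, keepdims=True)
        assert np.allclose(out.data, ((st + sp) * 0.5).data, atol=1e-9)

    def test_output_dim_is_hidden_dim(self):
        fusion = InterViewAttentionMean(16, 4, np.random.default_rng(0))
        xt = Tensor(np.zeros((3, 16)))
        xp = Tensor(np.zeros((5, 16)))
        assert fusion(xt, xp).shape == (1, 16)


class TestClassifierHead:
    def test_logistic_closed_form(self):
        emb = np.array([0.5, -1.0, 2.0])
        w = np.array([1.0, 0.2, -0.3])
        z = emb @ w + 0.1
        assert classify(emb, w, 0.1) == pytest.approx(1 / (1 + np.exp(-z)))

    def test_zero_embedding_zero_head_gives_half(self):
        assert classify(np.zeros(4), np.zeros(4), 0.0) == pytest.approx(0.5)


@pytest.fixture(scope="module")
def variant_datasets(small_corpus):
    splits = {k: small_corpus.subset(k) for k in ("train", "dev", "test")}
    return {v: prepare_datasets(splits, v, similarity_threshold=0.5)
            for v in ("similarity_baseline", "similarity_mv",
                      "kcg_baseline", "kcg_mv")}


class TestFullClassifiers:
    @pytest.mark.parametrize("variant", ["similarity_baseline", "similarity_mv",
                                         "kcg_baseline", "kcg_mv"])
    def test_forward_yields_probability(self, variant, variant_datasets):
        data = variant_datasets[variant]
        model = build_classifier(ModelConfig(variant=variant, hidden_dim=32),
                                 feat_dim=64, seed=0)
        for g in data["train"][:10]:
            p = model(g).item()
            assert 0.0 <= p <= 1.0

    @pytest.mark.parametrize("variant", ["similarity_mv", "kcg_mv"])
    def test_gradient_flow_reaches_every_parameter(self, variant,
                                                   variant_datasets):
        """No trainable tensor is detached from the loss (cross-attention
        branches included)."""
        data = variant_datasets[variant]["train"]
        model = build_classifier(ModelConfig(variant=variant, hidden_dim=16,
                                             dropout=0.0), feat_dim=64, seed=0)
        weights = class_weights([g.label for g in data])
        loss = None
        for g in data[:6]:
            term = weighted_bce(model(g), g.label, weights)
            loss = term if loss is None else loss + term
        loss.backward()
        for i, p in enumerate(model.parameters()):
            assert p.grad is not None and np.abs(p.grad).max() > 0, f"param {i}"

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(variant="similarity_mv", hidden_dim=10,
                        n_attention_heads=4)
        with pytest.raises(ValueError):
            ModelConfig(variant="nope")

    def test_state_round_trip(self, variant_datasets):
        g = variant_datasets["similarity_mv"]["train"][0]
        m1 = build_classifier(ModelConfig(variant="similarity_mv",
                                          hidden_dim=16), 64, seed=0)
        m2 = build_classifier(ModelConfig(variant="similarity_mv",
                                          hidden_dim=16), 64, seed=99)
        m2.load_state(m1.state())
        assert m1(g).item() == pytest.approx(m2(g).item(), abs=1e-15)
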