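"""Attention contracts: masks, head reduction, decoupling and fusion."""

import numpy as np
import pytest

from dtafuse.autograd import Tensor
from dtafuse.fusion import (
    CrossAttentionBlock,
    RegressionHead,
    decouple_attention,
    fuse,
    predict_affinity,
    scaled_dot_attention,
)
from dtafuse.sequence_encoder import FeatureMap


def _fm(values, mask=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape[:2], dtype=bool)
    return FeatureMap(values=Tensor(values), mask=mask)


class TestScaledDotAttention:
    def test_single_key_gives_unit_column(self, rng):
        q = Tensor(rng.normal(size=(3, 2)))
        k = Tensor(rng.normal(size=(1, 2)))
        v = Tensor(rng.normal(size=(1, 4)))
        out, attn = scaled_dot_attention(q, k, v, scale=1.0)
        np.testing.assert_allclose(attn.data, np.ones((3, 1)))
        np.testing.assert_allclose(out.data, np.repeat(v.data, 3, axis=0))

    def test_zero_logits_give_uniform_rows(self, rng):
        q = Tensor(np.zeros((2, 3)))
        k = Tensor(rng.normal(size=(5, 3)))
        v = Tensor(rng.normal(size=(5, 2)))
        _, attn = scaled_dot_attention(q, k, v, scale=2.0)
        np.testing.assert_allclose(attn.data, np.full((2, 5), 0.2))

    def test_hand_computed_softmax_map(self):
        # logits [[0, ln 3], [0, 0]] -> rows [[0.25, 0.75], [0.5, 0.5]]
        q = Tensor(np.array([[1.0], [0.0]]))
        k = Tensor(np.array([[0.0], [np.log(3.0)]]))
        v = Tensor(np.eye(2))
        _, attn = scaled_dot_attention(q, k, v, scale=1.0)
        np.testing.assert_allclose(attn.data, [[0.25, 0.75], [0.5, 0.5]], atol=1e-12)

    def test_masked_keys_get_zero_mass(self, rng):
        q = Tensor(rng.normal(size=(2, 3)))
        k = Tensor(rng.normal(size=(4, 3)))
        v = Tensor(rng.normal(size=(4, 2)))
        mask = np.array([True, True, False, True])
        _, attn = scaled_dot_attention(q, k, v, scale=1.0, key_mask=mask)
        np.testing.assert_array_equal(attn.data[:, 2], 0.0)
        np.testing.assert_allclose(attn.data.sum(axis=1), 1.0, atol=1e-12)

    def test_all_keys_masked_rejected(self, rng):
        q = Tensor(rng.normal(size=(1, 2)))
        kv = Tensor(rng.normal(size=(3, 2)))
        with pytest.raises(ValueError):
            scaled_dot_attention(q, kv, kv, 1.0, key_mask=np.zeros(3, dtype=bool))

    def test_key_value_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            scaled_dot_attention(Tensor(np.ones((1, 2))), Tensor(np.ones((3, 2))),
                                 Tensor(np.ones((4, 2))), 1.0)


class TestCrossMultiHead:
    def _block(self, heads, seed=0, **kw):
        args = dict(query_dim=6, kv_dim=5, attn_dim=8, heads=heads, dropout=0.0,
                    rng=np.random.default_rng(seed))
        args.update(kw)
        return CrossAttentionBlock(**args).eval()

    def test_single_head_reduces_to_scaled_dot_attention(self, rng):
        block = self._block(heads=1)
        q_fm = _fm(rng.normal(size=(1, 4, 6)))
        kv_fm = _fm(rng.normal(size=(1, 7, 5)))
        out, attn = block(q_fm, kv_fm)
        q = np.maximum(q_fm.values.data @ block.q_in.weight.data + block.q_in.bias.data, 0)
        kv = np.maximum(kv_fm.values.data @ block.kv_in.weight.data + block.kv_in.bias.data, 0)
        oracle_out, oracle_attn = scaled_dot_attention(
            Tensor(q[0] @ block.w_q.weight.data), Tensor(kv[0] @ block.w_k.weight.data),
            Tensor(kv[0] @ block.w_v.weight.data), block.scale)
        np.testing.assert_allclose(attn.data[0], oracle_attn.data, atol=1e-6)
        expected_out = oracle_out.data @ block.w_o.weight.data + block.w_o.bias.data
        np.testing.assert_allclose(out.data[0], expected_out, atol=1e-6)

    def test_identical_queries_give_identical_map_rows(self, rng):
        block = self._block(heads=2)
        row = rng.normal(size=6)
        q_fm = _fm(np.tile(row, (1, 3, 1)))
        kv_fm = _fm(rng.normal(size=(1, 5, 5)))
        _, attn = block(q_fm, kv_fm)
        np.testing.assert_allclose(attn.data[0, 0], attn.data[0, 1], atol=1e-12)
        np.testing.assert_allclose(attn.data[0, 0], attn.data[0, 2], atol=1e-12)

    def test_matches_loop_over_heads_oracle(self, rng):
        h = 8
        block = self._block(heads=h, attn_dim=16)
        q_fm = _fm(rng.normal(size=(2, 3, 6)))
        kv_fm = _fm(rng.normal(size=(2, 5, 5)))
        out, attn = block(q_fm, kv_fm)
        dh = 16 // h
        q = np.maximum(q_fm.values.data @ block.q_in.weight.data + block.q_in.bias.data, 0)
        kv = np.maximum(kv_fm.values.data @ block.kv_in.weight.data + block.kv_in.bias.data, 0)
        for b in range(2):
            maps, outs = [], []
            for i in range(h):
                wq = block.w_q.weight.data[:, i * dh:(i + 1) * dh]
                wk = block.w_k.weight.data[:, i * dh:(i + 1) * dh]
                wv = block.w_v.weight.data[:, i * dh:(i + 1) * dh]
                logits = (q[b] @ wq) @ (kv[b] @ wk).T / block.scale
                e = np.exp(logits - logits.max(axis=1, keepdims=True))
                m = e / e.sum(axis=1, keepdims=True)
                maps.append(m)
                outs.append(m @ (kv[b] @ wv))
            np.testing.assert_allclose(attn.data[b], np.mean(maps, axis=0), atol=1e-6)
            merged = np.concatenate(outs, axis=1)
            np.testing.assert_allclose(
                out.data[b], merged @ block.w_o.weight.data + block.w_o.bias.data,
                atol=1e-6)

    def test_head_count_must_divide_width(self):
        with pytest.raises(ValueError):
            self._block(heads=3)

    def test_rows_sum_to_one_over_unmasked_keys(self, rng):
        block = self._block(heads=2)
        q_fm = _fm(rng.normal(size=(1, 3, 6)))
        mask = np.array([[True, True, True, False, False]])
        kv_fm = _fm(rng.normal(size=(1, 5, 5)), mask)
        _, attn = block(q_fm, kv_fm)
        np.testing.assert_allclose(attn.data[0].sum(axis=1), 1.0, atol=1e-5)
        np.testing.assert_array_equal(attn.data[0][:, 3:], 0.0)


class TestDecouple:
    def test_uniform_maps_give_constant_weights(self):
        a1 = Tensor(np.full((1, 3, 4), 0.25))
        a2 = Tensor(np.full((1, 2, 4), 0.25))
        m3, m2, m4 = (np.ones((1, 3), bool), np.ones((1, 2), bool), np.ones((1, 4), bool))
        ad1, ad2, ap = decouple_attention(a1, a2, m3, m2, m4)
        np.testing.assert_allclose(ad1.data, 0.25)
        np.testing.assert_allclose(ad2.data, 0.25)
        np.testing.assert_allclose(ap.data, 0.25)

    def test_concentrated_column_dominates_protein_weight(self):
        a1 = np.zeros((1, 3, 4))
        a1[:, :, 2] = 1.0
        a2 = np.zeros((1, 2, 4))
        a2[:, :, 2] = 1.0
        _, _, ap = decouple_attention(
            Tensor(a1), Tensor(a2), np.ones((1, 3), bool), np.ones((1, 2), bool),
            np.ones((1, 4), bool))
        assert ap.data[0].argmax() == 2

    def test_matches_row_column_mean_oracle(self, rng):
        a1 = rng.uniform(size=(1, 3, 4))
        a2 = rng.uniform(size=(1, 2, 4))
        ad1, ad2, ap = decouple_attention(
            Tensor(a1), Tensor(a2), np.ones((1, 3), bool), np.ones((1, 2), bool),
            np.ones((1, 4), bool))
        np.testing.assert_allclose(ad1.data[0], a1[0].mean(axis=1), atol=1e-9)
        np.testing.assert_allclose(ad2.data[0], a2[0].mean(axis=1), atol=1e-9)
        np.testing.assert_allclose(
            ap.data[0], np.concatenate([a1[0], a2[0]]).mean(axis=0), atol=1e-9)

    def test_protein_axis_mismatch_rejected(self):
        with pytest.raises(ValueError):
            decouple_attention(Tensor(np.ones((1, 2, 4))), Tensor(np.ones((1, 2, 5))),
                               np.ones((1, 2), bool), np.ones((1, 2), bool),
                               np.ones((1, 4), bool))

    def test_weights_nonnegative_for_attention_maps(self, rng):
        a1 = rng.dirichlet(np.ones(4), size=(1, 3))
        a2 = rng.dirichlet(np.ones(4), size=(1, 2))
        ad1, ad2, ap = decouple_attention(
            Tensor(a1), Tensor(a2), np.ones((1, 3), bool), np.ones((1, 2), bool),
            np.ones((1, 4), bool))
        assert (ad1.data >= 0).all() and (ad2.data >= 0).all() and (ap.data >= 0).all()


class TestFuse:
    def test_unit_weights_give_plain_max_pools(self, rng):
        seq = _fm(rng.normal(size=(1, 4, 3)))
        nodes = _fm(rng.normal(size=(1, 2, 5)))
        prot = _fm(rng.normal(size=(1, 6, 3)))
        ones = lambda n: Tensor(np.ones((1, n)))
        i_dp = fuse(ones(4), seq, ones(2), nodes, ones(6), prot)
        expected = np.concatenate([
            seq.values.data[0].max(axis=0), nodes.values.data[0].max(axis=0),
            prot.values.data[0].max(axis=0)])
        np.testing.assert_allclose(i_dp.data[0], expected, atol=1e-6)

    def test_zero_drug_weights_zero_that_segment(self, rng):
        seq = _fm(np.abs(rng.normal(size=(1, 4, 3))))
        nodes = _fm(rng.normal(size=(1, 2, 5)))
        prot = _fm(rng.normal(size=(1, 6, 3)))
        i_dp = fuse(Tensor(np.zeros((1, 4))), seq, Tensor(np.ones((1, 2))), nodes,
                    Tensor(np.ones((1, 6))), prot)
        np.testing.assert_array_equal(i_dp.data[0, :3], 0.0)

    def test_segments_match_per_channel_max_oracle(self, rng):
        seq = _fm(rng.normal(size=(1, 4, 3)))
        nodes = _fm(rng.normal(size=(1, 5, 2)))
        prot = _fm(rng.normal(size=(1, 6, 3)))
        w_seq = Tensor(rng.uniform(size=(1, 4)))
        w_nodes = Tensor(rng.uniform(size=(1, 5)))
        w_prot = Tensor(rng.uniform(size=(1, 6)))
        i_dp = fuse(w_seq, seq, w_nodes, nodes, w_prot, prot).data[0]
        oracle = np.concatenate([
            (seq.values.data[0] * w_seq.data[0][:, None]).max(axis=0),
            (nodes.values.data[0] * w_nodes.data[0][:, None]).max(axis=0),
            (prot.values.data[0] * w_prot.data[0][:, None]).max(axis=0)])
        np.testing.assert_allclose(i_dp, oracle, atol=1e-6)


class TestRegressionHead:
    def test_zero_input_zero_weights_give_zero(self, rng):
        head = RegressionHead(4, [8, 8, 4], dropout=0.0, rng=rng).eval()
        for layer in head.hidden_layers + [head.out]:
            layer.weight.data[:] = 0.0
            layer.bias.data[:] = 0.0
        out = predict_affinity(Tensor(np.zeros((2, 4))), head)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_affine_case_is_exact(self, rng):
        head = RegressionHead(3, [3, 3, 3], dropout=0.0, rng=rng).eval()
        # reduce to a single affine map: make hidden layers the identity
        for layer in head.hidden_layers:
            layer.weight.data = np.eye(3)
            layer.bias.data[:] = 0.0
        x = np.abs(rng.normal(size=(4, 3)))  # positive, so ReLU is transparent
        out = predict_affinity(Tensor(x), head)
        np.testing.assert_allclose(
            out.data, (x @ head.out.weight.data + head.out.bias.data).ravel(), atol=1e-12)

    def test_eval_mode_is_deterministic(self, rng):
        head = RegressionHead(5, [8, 8, 4], dropout=0.5, rng=rng).eval()
        x = Tensor(rng.normal(size=(3, 5)))
        a = predict_affinity(x, head).data
        b = predict_affinity(x, head).data
        np.testing.assert_array_equal(a, b)

    def test_width_mismatch_rejected(self, rng):
        head = RegressionHead(5, [8, 8, 4], dropout=0.0, rng=rng)
        with pytest.raises(ValueError):
            predict_affinity(Tensor(np.zeros((1, 6))), head)
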