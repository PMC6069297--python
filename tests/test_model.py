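"""Network components against brute-force oracles, shape contracts,
determinism, and the batched/functional dual-route consistency."""

import numpy as np
import pytest

from cid_rpcnn.knowledge import featurize_pair
from cid_rpcnn.model import (
    ModelConfig,
    RPCNNParams,
    attention_pool,
    convolve,
    document_repr,
    embed,
    forward,
    instance_repr,
    make_batch,
    max_pool,
    score,
)
from conftest import small_config


# -- independent oracles (straight loops, no vectorisation) ----------------


def convolve_oracle(x, filters, biases):
    q, k, d = filters.shape
    p = x.shape[0] - k + 1
    out = np.zeros((q, p))
    for t in range(q):
        for i in range(p):
            acc = 0.0
            for a in range(k):
                for b in range(d):
                    acc += filters[t, a, b] * x[i + a, b]
            out[t, i] = max(acc + biases[t], 0.0)
    return out


def max_pool_oracle(f):
    if f.shape[1] == 0:
        return np.zeros(f.shape[0])
    return np.array([max(row) for row in f])


def attention_pool_oracle(f, m, w):
    q, p = f.shape
    if p == 0:
        return np.zeros(q)
    g = np.zeros((p, w.shape[1]))
    for i in range(p):
        for j in range(w.shape[1]):
            for a in range(q):
                for b in range(q):
                    g[i, j] += f[a, i] * m[a, b] * w[b, j]
    a_mat = np.exp(g - g.max(axis=0))
    a_mat = a_mat / a_mat.sum(axis=0)
    fa = f @ a_mat
    return np.array([max(row) for row in fa])


class TestOracleEquivalence:
    def test_convolution_matches_brute_force(self, rng):
        for _ in range(40):
            q = int(rng.integers(1, 5))
            k = int(rng.integers(1, 4))
            l = int(rng.integers(k, 11))
            d = int(rng.integers(1, 5))
            x = rng.standard_normal((l, d))
            filters = rng.standard_normal((q, k, d))
            biases = rng.standard_normal(q)
            got = convolve(x, filters, biases)
            assert np.allclose(got, convolve_oracle(x, filters, biases), atol=1e-10)

    def test_pooling_matches_brute_force(self, rng):
        for _ in range(40):
            q, p = int(rng.integers(1, 5)), int(rng.integers(1, 8))
            f = rng.standard_normal((q, p))
            assert np.allclose(max_pool(f), max_pool_oracle(f))
            m = rng.standard_normal((q, q))
            w = rng.standard_normal((q, 2))
            assert np.allclose(
                attention_pool(f, m, w), attention_pool_oracle(f, m, w), atol=1e-10
            )

    def test_small_integer_attention_case(self):
        f = np.array([[1.0, 0.0, 2.0], [0.0, 3.0, 1.0]])
        m = np.array([[1.0, 0.0], [0.0, 2.0]])
        w = np.eye(2)
        assert np.allclose(
            attention_pool(f, m, w), attention_pool_oracle(f, m, w)
        )


class TestConvolveEdgeCases:
    def test_zero_input_zero_bias_is_zero(self):
        out = convolve(np.zeros((6, 3)), np.zeros((2, 2, 3)), np.zeros(2))
        assert (out == 0).all()

    def test_identity_filter_reproduces_rectified_row(self, rng):
        x = rng.standard_normal((5, 4))
        filters = np.zeros((1, 1, 4))
        filters[0, 0, 2] = 1.0
        out = convolve(x, filters, np.zeros(1))
        assert np.allclose(out[0], np.maximum(x[:, 2], 0.0))

    def test_sequence_shorter_than_filter_errors(self):
        with pytest.raises(ValueError, match="filter size"):
            convolve(np.zeros((2, 3)), np.zeros((1, 3, 3)), np.zeros(1))


class TestAttentionProperties:
    def test_attention_matrix_columns_sum_to_one(self, rng):
        g = rng.standard_normal((7, 2))
        a = np.exp(g) / np.exp(g).sum(axis=0)
        assert np.allclose(a.sum(axis=0), 1.0)

    def test_zero_m_reduces_to_row_mean(self, rng):
        f = rng.standard_normal((4, 6))
        out = attention_pool(f, np.zeros((4, 4)), np.eye(4)[:, :2])
        assert np.allclose(out, f.mean(axis=1))

    def test_one_hot_attention_recovers_max_pool(self, rng):
        """max pooling is the limit of attention with a one-hot column."""
        f = rng.standard_normal((3, 5))
        for t in range(3):
            j = int(np.argmax(f[t]))
            one_hot = np.zeros((5, 1))
            one_hot[j] = 1.0
            assert np.isclose((f @ one_hot)[t, 0], max_pool(f)[t])

    def test_empty_feature_map_pools_to_zero(self):
        f = np.zeros((3, 0))
        assert (attention_pool(f, np.zeros((3, 3)), np.eye(3)[:, :2]) == 0).all()
        assert (max_pool(f) == 0).all()


class TestShapeContracts:
    def test_published_dimensions(self, tiny_setup):
        """The stated hyperparameters give 40 / 900 / 150 / 120 / 270 dims."""
        cfg = ModelConfig()
        assert cfg.token_dim == 40
        assert cfg.z_dim == 900
        assert cfg.fused_dim == 270
        params = RPCNNParams(
            cfg,
            vocab_size=len(tiny_setup["vocab"]),
            n_pos_buckets=2 * tiny_setup["l"],
            kb_dim=7,
        )
        inst = tiny_setup["cands"][0].encoded[0]
        x = embed(inst, params)
        assert x.shape == (inst.length, 40)
        z = instance_repr(inst, params, cfg)
        assert z.shape == (900,)
        h = document_repr([z], params, cfg)
        assert h.shape == (150,)
        assert params["W_k"].data.shape == (7, 120)
        assert params["u"].data.shape == (270, 1)

    def test_non_piecewise_width(self, tiny_setup):
        cfg = small_config(use_piecewise=False)
        assert cfg.z_dim == 2 * cfg.filters_per_size
        inst = tiny_setup["cands"][0].encoded[0]
        params = RPCNNParams(cfg, len(tiny_setup["vocab"]), 2 * tiny_setup["l"])
        assert instance_repr(inst, params, cfg).shape == (cfg.z_dim,)

    def test_embed_locality_in_position_tracks(self, tiny_setup):
        import copy

        inst = copy.deepcopy(tiny_setup["cands"][0].encoded[0])
        params = tiny_setup["params"]
        x0 = embed(inst, params)
        inst.da_ids[2] = (inst.da_ids[2] + 1) % params.n_pos_buckets
        x1 = embed(inst, params)
        d_w, d_pc = params.config.d_w, params.config.d_pc
        assert (x0[:2] == x1[:2]).all() and (x0[3:] == x1[3:]).all()
        assert (x0[2, : d_w + d_pc] == x1[2, : d_w + d_pc]).all()
        assert (x0[2, d_w + d_pc :] != x1[2, d_w + d_pc :]).any()

    def test_embed_out_of_range_errors(self, tiny_setup):
        import copy

        inst = copy.deepcopy(tiny_setup["cands"][0].encoded[0])
        inst.word_ids[0] = 10**6
        with pytest.raises(IndexError):
            embed(inst, tiny_setup["params"])


class TestDualRoute:
    def test_batched_forward_equals_functional_composition(self, tiny_setup):
        """The vectorised training path reproduces the per-instance pipeline
        embed -> convolve -> pool -> recurrence -> score exactly."""
        cfg, params = tiny_setup["cfg"], tiny_setup["params"]
        cands = tiny_setup["cands"][:6]
        batch = make_batch(cands, tiny_setup["kbits"][:6])
        batched = forward(batch, params, cfg).sigmoid().data
        for i, cand in enumerate(cands):
            zs = [instance_repr(e, params, cfg) for e in cand.encoded]
            h = document_repr(zs, params, cfg)
            kf = featurize_pair(
                cand.chem_id, cand.dis_id, tiny_setup["tables"], tiny_setup["layout"]
            )
            assert np.isclose(score(h, kf, params, cfg), batched[i], atol=1e-10)

    @pytest.mark.parametrize(
        "flags",
        [
            dict(use_piecewise=False, use_attention=False, use_rnn=False),
            dict(use_attention=False),
            dict(use_piecewise=False),
            dict(use_knowledge=False),
        ],
    )
    def test_dual_route_across_ablation_variants(self, tiny_setup, flags):
        cfg = small_config(**flags)
        l, vocab = tiny_setup["l"], tiny_setup["vocab"]
        params = RPCNNParams(
            cfg, len(vocab), 2 * l, kb_dim=tiny_setup["layout"].width
        )
        cand = tiny_setup["cands"][1]
        batch = make_batch([cand], tiny_setup["kbits"][1:2])
        batched = float(forward(batch, params, cfg).sigmoid().data[0])
        zs = [instance_repr(e, params, cfg) for e in cand.encoded]
        h = document_repr(zs, params, cfg)
        kf = featurize_pair(
            cand.chem_id, cand.dis_id, tiny_setup["tables"], tiny_setup["layout"]
        )
        assert np.isclose(score(h, kf, params, cfg), batched, atol=1e-10)


class TestRecurrence:
    def test_single_instance_state_length(self, tiny_setup):
        cfg, params = tiny_setup["cfg"], tiny_setup["params"]
        z = instance_repr(tiny_setup["cands"][0].encoded[0], params, cfg)
        h = document_repr([z], params, cfg)
        assert h.shape == (cfg.hidden,)

    def test_state_accumulates_over_repeats(self, tiny_setup):
        cfg, params = tiny_setup["cfg"], tiny_setup["params"]
        z = instance_repr(tiny_setup["cands"][0].encoded[0], params, cfg)
        h1 = document_repr([z], params, cfg)
        h2 = document_repr([z, z], params, cfg)
        assert not np.allclose(h1, h2)

    def test_order_sensitivity(self, tiny_setup):
        cfg, params = tiny_setup["cfg"], tiny_setup["params"]
        cand = next(c for c in tiny_setup["cands"] if len(c.encoded) >= 2)
        zs = [instance_repr(e, params, cfg) for e in cand.encoded]
        assert not np.allclose(
            document_repr(zs, params, cfg), document_repr(zs[::-1], params, cfg)
        )

    def test_empty_candidate_errors(self, tiny_setup):
        with pytest.raises(ValueError):
            document_repr([], tiny_setup["params"], tiny_setup["cfg"])

    def test_cnn_baseline_uses_only_last_instance(self, tiny_setup):
        cfg = small_config(use_rnn=False)
        params = RPCNNParams(
            cfg, len(tiny_setup["vocab"]), 2 * tiny_setup["l"],
            kb_dim=tiny_setup["layout"].width,
        )
        cand = next(c for c in tiny_setup["cands"] if len(c.encoded) >= 2)
        zs = [instance_repr(e, params, cfg) for e in cand.encoded]
        full = document_repr(zs, params, cfg)
        last_only = document_repr(zs[-1:], params, cfg)
        assert np.allclose(full, last_only)


class TestScore:
    def test_zero_logit_is_half(self, tiny_setup):
        cfg = small_config(use_knowledge=False)
        params = RPCNNParams(cfg, 10, 10)
        params["u"].data[:] = 0.0
        params["b_u"].data[:] = 0.0
        h = np.ones(cfg.hidden)
        assert score(h, None, params, cfg) == 0.5

    def test_monotone_in_logit_and_strictly_inside_unit_interval(self, tiny_setup):
        cfg, params = tiny_setup["cfg"], tiny_setup["params"]
        cand = tiny_setup["cands"][0]
        zs = [instance_repr(e, params, cfg) for e in cand.encoded]
        h = document_repr(zs, params, cfg)
        kf = featurize_pair(
            cand.chem_id, cand.dis_id, tiny_setup["tables"], tiny_setup["layout"]
        )
        s0 = score(h, kf, params, cfg)
        assert 0.0 < s0 < 1.0
        params["b_u"].data[:] += 2.0
        assert score(h, kf, params, cfg) > s0
        params["b_u"].data[:] -= 2.0


class TestDeterminism:
    def test_same_seed_identical_params_and_scores(self, tiny_setup):
        cfg = small_config(seed=11)
        l, vocab = tiny_setup["l"], tiny_setup["vocab"]
        kb = tiny_setup["layout"].width
        p1 = RPCNNParams(cfg, len(vocab), 2 * l, kb_dim=kb)
        p2 = RPCNNParams(cfg, len(vocab), 2 * l, kb_dim=kb)
        for name, t in p1.items():
            assert np.array_equal(t.data, p2[name].data)
        batch = make_batch(tiny_setup["cands"][:3], tiny_setup["kbits"][:3])
        assert np.array_equal(
            forward(batch, p1, cfg).data, forward(batch, p2, cfg).data
        )

    def test_attention_init_conventions(self):
        cfg = small_config(use_attention=True)
        params = RPCNNParams(cfg, 10, 10, kb_dim=2)
        q, nc = cfg.filters_per_size, cfg.n_classes
        assert np.array_equal(params["W_classes"].data, np.eye(q)[:, :nc])
        assert params["M"].data.shape == (q, q)


def test_checkpoint_round_trip(tmp_path, tiny_setup):
    cfg, params = tiny_setup["cfg"], tiny_setup["params"]
    path = tmp_path / "model.npz"
    params.save(path, vocab_words=["a", "b"])
    loaded = RPCNNParams.load(path)
    assert loaded.config == cfg
    assert loaded.vocab_words == ["a", "b"]
    for name, t in params.items():
        assert np.array_equal(t.data, loaded[name].data)
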