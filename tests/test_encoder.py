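import numpy as np
import pytest

from ablm.encoder import (
    DisentangledAttentionWeights,
    Encoder,
    EncoderConfig,
    FeedForwardWeights,
    attention_output,
    attention_scores,
    feed_forward,
    rel_index,
    rel_index_matrix,
)


def small_cfg(**kw):
    base = dict(n_layers=1, d_model=8, n_heads=2, d_ff=16, k_max=2, max_len=64)
    base.update(kw)
    return EncoderConfig(**base)


def rand_weights(rng, d, d_k):
    return DisentangledAttentionWeights(
        *(rng.normal(size=(d, d_k)) for _ in range(5))
    )


class TestRelIndex:
    def test_diagonal(self):
        assert rel_index(5, 5, 128) == 128

    def test_clamped_low(self):
        assert rel_index(0, 300, 128) == 0

    def test_small_positive(self):
        assert rel_index(5, 2, 128) == 131

    @pytest.mark.parametrize("k", [1, 2, 128])
    def test_exhaustive_clamp_oracle(self, k):
        # brute-force clamp loop over [0, 300)^2
        i = np.arange(300)
        mat = rel_index_matrix(300, k)
        for ii in range(0, 300, 7):
            for jj in range(0, 300, 7):
                diff = ii - jj
                expect = (-k if diff < -k else k if diff > k else diff) + k
                assert mat[ii, jj] == expect
                assert rel_index(ii, jj, k) == expect

    def test_k_must_be_positive(self):
        with pytest.raises(ValueError):
            rel_index(0, 0, 0)

    def test_saturation_onset_at_default_k(self):
        k = EncoderConfig().k_max
        s = 0
        while rel_index(s, 0, k) != rel_index(s + 1, 0, k):
            s += 1
        assert s == 128


class TestAttentionScores:
    def test_zero_position_weights_reduce_to_content(self, rng):
        cfg = small_cfg()
        H = rng.normal(size=(5, 8))
        P = rng.normal(size=(2 * cfg.k_max + 1, 8))
        w = rand_weights(rng, 8, 4)
        w.w_qr[:] = 0
        w.w_kr[:] = 0
        scores = attention_scores(H, P, w, cfg)
        expect = (H @ w.w_qc) @ (H @ w.w_kc).T
        assert np.allclose(scores, expect, atol=1e-10)

    def test_single_token(self, rng):
        cfg = small_cfg()
        H = rng.normal(size=(1, 8))
        P = rng.normal(size=(2 * cfg.k_max + 1, 8))
        w = rand_weights(rng, 8, 4)
        scores = attention_scores(H, P, w, cfg)
        assert scores.shape == (1, 1)
        V = rng.normal(size=(1, 4))
        assert np.allclose(attention_output(scores, V, cfg), V)

    @pytest.mark.parametrize("variant", ["as_printed", "deberta_original"])
    def test_against_double_loop_oracle(self, variant, rng):
        cfg = small_cfg(p2c_variant=variant)
        for _ in range(20):
            n, d, d_k = 4, 8, 4
            H = rng.normal(size=(n, d))
            P = rng.normal(size=(2 * cfg.k_max + 1, d))
            w = rand_weights(rng, d, d_k)
            got = attention_scores(H, P, w, cfg)
            qc, kc = H @ w.w_qc, H @ w.w_kc
            kr = P @ w.w_kr
            oracle = np.zeros((n, n))
            for i in range(n):
                for j in range(n):
                    oracle[i, j] = qc[i] @ kc[j]
                    oracle[i, j] += qc[i] @ kr[rel_index(i, j, cfg.k_max)]
                    if variant == "as_printed":
                        oracle[i, j] += (H[i] @ w.w_qr) @ kc[j]
                    else:
                        oracle[i, j] += (P[rel_index(j, i, cfg.k_max)] @ w.w_qr) @ kc[j]
            assert np.allclose(got, oracle, rtol=1e-6, atol=1e-9)

    def test_shape_mismatch_rejected(self, rng):
        cfg = small_cfg()
        with pytest.raises(ValueError, match="w_qc"):
            attention_scores(rng.normal(size=(5, 6)), None, rand_weights(rng, 8, 4), cfg)


class TestAttentionOutput:
    def test_uniform_scores_average_values(self, rng):
        cfg = small_cfg()
        V = rng.normal(size=(6, 4))
        out = attention_output(np.zeros((6, 6)), V, cfg)
        assert np.allclose(out, np.tile(V.mean(axis=0), (6, 1)))

    def test_saturation_selects_one_row(self, rng):
        cfg = small_cfg()
        V = rng.normal(size=(3, 4))
        scores = np.zeros((3, 3))
        scores[:, 1] = 1e4
        out = attention_output(scores, V, cfg)
        assert np.allclose(out, np.tile(V[1], (3, 1)), atol=1e-5)

    def test_softmax_by_hand(self, rng):
        cfg = small_cfg()
        scores = rng.normal(size=(4, 4))
        V = rng.normal(size=(4, 5))
        z = scores / np.sqrt(3 * cfg.d_k)
        probs = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        assert np.allclose(attention_output(scores, V, cfg), probs @ V, atol=1e-10)

    def test_scale_is_sqrt_3dk_in_relative_mode(self):
        assert small_cfg().score_scale == pytest.approx(1 / np.sqrt(3 * 4))
        abs_cfg = small_cfg(position_mode="absolute_learned")
        assert abs_cfg.score_scale == pytest.approx(1 / np.sqrt(4))


class TestFeedForward:
    def test_zero_weights(self):
        w = FeedForwardWeights(np.zeros((4, 8)), np.zeros(8), np.zeros((8, 4)), np.zeros(4))
        assert np.allclose(feed_forward(np.ones((3, 4)), w), 0.0)

    def test_affine_with_relu_positive(self, rng):
        # positive inputs through identity-like weights reproduce the affine map
        w = FeedForwardWeights(np.eye(4, 8), np.zeros(8), np.eye(8, 4), np.ones(4))
        x = np.abs(rng.normal(size=(3, 4)))
        assert np.allclose(feed_forward(x, w, "relu"), x + 1.0)

    def test_against_matmul_oracle(self, rng):
        w = FeedForwardWeights(
            rng.normal(size=(4, 8)), rng.normal(size=8), rng.normal(size=(8, 4)), rng.normal(size=4)
        )
        x = rng.normal(size=(5, 4))
        expect = np.maximum(x @ w.w1 + w.b1, 0) @ w.w2 + w.b2
        assert np.allclose(feed_forward(x, w, "relu"), expect, atol=1e-10)


class TestEncoderModel:
    def test_deterministic_init_and_forward(self):
        cfg = small_cfg()
        ids = np.array([[2, 7, 8, 9, 3]])
        a = Encoder(cfg, seed=5).encode(ids)
        b = Encoder(cfg, seed=5).encode(ids)
        assert np.array_equal(a, b)

    def test_out_of_vocab_rejected(self):
        with pytest.raises(ValueError, match="vocabulary"):
            Encoder(small_cfg(), seed=0).encode(np.array([[99]]))

    def test_translation_equivariance_relative(self):
        enc = Encoder(small_cfg(), seed=1)
        ids = np.array([[5, 6, 7, 8, 9, 10]])
        a = enc.encode(ids, position_offset=0)
        b = enc.encode(ids, position_offset=5)
        assert np.allclose(a, b)

    def test_translation_sensitivity_absolute(self):
        enc = Encoder(small_cfg(position_mode="absolute_learned"), seed=1)
        ids = np.array([[5, 6, 7, 8, 9, 10]])
        a = enc.encode(ids, position_offset=0)
        b = enc.encode(ids, position_offset=5)
        assert not np.allclose(a, b)

    def test_layer_output_finite_and_shaped(self):
        enc = Encoder(small_cfg(n_layers=3), seed=2)
        ids = np.random.default_rng(0).integers(0, 25, size=(2, 9))
        out = enc.encode(ids)
        assert out.shape == (2, 9, 8)
        assert np.isfinite(out).all()

    def test_model_scores_match_functional_route(self, rng):
        """The batched training path reproduces the single-head functional ops."""
        cfg = small_cfg(n_heads=1)
        enc = Encoder(cfg, seed=3)
        ids = np.array([[4, 9, 12, 6]])
        # functional route on the same parameters, first layer
        from ablm._nn import Tensor

        x = enc.params["embed"].embed(ids)
        x = x.layer_norm(enc.params["emb_ln_g"], enc.params["emb_ln_bias"]).data[0]
        P = enc.params["rel_P"].layer_norm(
            enc.params["rel_ln_g"], enc.params["rel_ln_bias"]
        ).data
        w = DisentangledAttentionWeights(
            enc.params["l0.w_qc"].data,
            enc.params["l0.w_kc"].data,
            enc.params["l0.w_vc"].data,
            enc.params["l0.w_qr"].data,
            enc.params["l0.w_kr"].data,
        )
        expected = attention_output(
            attention_scores(x, P, w, cfg), x @ w.w_vc, cfg
        )
        # reproduce the model's internal pre-projection attention output
        b, n = ids.shape
        delta = rel_index_matrix(n, cfg.k_max)
        xt = Tensor(x[None, :, :])
        qc = enc._split_heads(xt @ enc.params["l0.w_qc"], b, n) * cfg.score_scale
        kc = enc._split_heads(xt @ enc.params["l0.w_kc"], b, n)
        v = enc._split_heads(xt @ enc.params["l0.w_vc"], b, n)
        rel_p = enc.params["rel_P"].layer_norm(enc.params["rel_ln_g"], enc.params["rel_ln_bias"])
        m = 2 * cfg.k_max + 1
        kr = (rel_p @ enc.params["l0.w_kr"]).reshape(m, 1, cfg.d_k).transpose(1, 0, 2)
        scores = qc @ kc.transpose(0, 1, 3, 2) + (qc @ kr.transpose(0, 2, 1)).gather_last(delta)
        qr = enc._split_heads(xt @ enc.params["l0.w_qr"], b, n) * cfg.score_scale
        scores = scores + qr @ kc.transpose(0, 1, 3, 2)
        got = (scores.softmax(axis=-1) @ v).data[0, 0]
        assert np.allclose(got, expected, atol=1e-4)

    def test_mlm_logits_shape_and_oracle(self):
        enc = Encoder(small_cfg(), seed=0)
        ids = np.array([[2, 5, 6, 3]])
        hidden = enc.forward(ids)
        logits = enc.mlm_logits(hidden)
        assert logits.shape == (1, 4, 25)
        expect = hidden.data @ enc.params["mlm_w"].data + enc.params["mlm_bias"].data
        assert np.allclose(logits.data, expect, atol=1e-5)

    def test_zero_mlm_weights_uniform(self):
        enc = Encoder(small_cfg(), seed=0)
        enc.params["mlm_w"].data[:] = 0
        enc.params["mlm_bias"].data[:] = 0
        logits = enc.mlm_logits(enc.forward(np.array([[2, 5, 3]]))).data[0]
        assert np.allclose(logits, logits[0, 0])


class TestCheckpoint:
    def test_save_load_save_byte_identical(self, tmp_path):
        enc = Encoder(small_cfg(), seed=9)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        enc.save(d1)
        loaded = Encoder.load(d1)
        loaded.save(d2)
        assert (d1 / "params.npz").read_bytes() == (d2 / "params.npz").read_bytes()
        assert (d1 / "meta.json").read_text() == (d2 / "meta.json").read_text()

    def test_round_trip_forward_identical(self, tmp_path):
        enc = Encoder(small_cfg(), seed=9)
        enc.save(tmp_path / "ck")
        loaded = Encoder.load(tmp_path / "ck")
        ids = np.array([[2, 8, 9, 3]])
        assert np.array_equal(enc.encode(ids), loaded.encode(ids))

    def test_vocabulary_serialized(self, tmp_path):
        enc = Encoder(small_cfg(), seed=0)
        enc.save(tmp_path / "ck")
        loaded = Encoder.load(tmp_path / "ck")
        assert loaded.alphabet == enc.alphabet

    def test_param_hash_stable(self):
        a = Encoder(small_cfg(), seed=4)
        b = Encoder(small_cfg(), seed=4)
        assert a.param_hash() == b.param_hash()
        b.params["mlm_w"].data[0, 0] += 1
        assert a.param_hash() != b.param_hash()


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
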