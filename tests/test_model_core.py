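"""Architecture behaviour: positional encoding, attention algebra, the three
transformer submodules and the assembled model variants."""

import numpy as np
import pytest

from chromoformer import (
    Chromoformer,
    ChromoformerDiff,
    ConfigurationError,
    InputError,
    ModelConfig,
    positional_encoding,
    scaled_dot_attention,
)
from chromoformer.autodiff import Tensor
from chromoformer.model import (
    EmbeddingTransformer,
    PairwiseTransformer,
    RegulationLayer,
    RegulationTransformer,
    load_checkpoint,
    save_checkpoint,
)
from chromoformer.train import collate


class TestPositionalEncoding:
    def test_row_zero_alternates_zero_one(self):
        P = positional_encoding(4, 8)
        assert np.allclose(P[0], [0, 1, 0, 1, 0, 1, 0, 1])

    def test_first_component_is_sin_of_position(self):
        P = positional_encoding(4, 8)
        assert np.isclose(P[1, 0], np.sin(1.0))
        assert np.isclose(P[2, 0], np.sin(2.0))

    def test_inner_products_depend_only_on_distance(self):
        P = positional_encoding(512, 128)
        G = P @ P.T
        # G must be Toeplitz: comparing each element with its diagonal
        # neighbour covers every (a, b) vs (a+s, b+s) pair transitively
        assert np.abs(G[:-1, :-1] - G[1:, 1:]).max() < 1e-9

    def test_odd_dimension_rejected(self):
        with pytest.raises(ConfigurationError):
            positional_encoding(4, 7)


class TestScaledDotAttention:
    def test_identical_keys_give_uniform_weights(self, rng):
        Q = Tensor(rng.normal(size=(1, 1, 3, 4)))
        K = Tensor(np.ones((1, 1, 5, 4)))
        V = Tensor(rng.normal(size=(1, 1, 5, 4)))
        _, w = scaled_dot_attention(Q, K, V, 4)
        assert np.allclose(w.data, 0.2)

    def test_two_token_toy_matches_hand_softmax(self, rng):
        q = rng.normal(size=4)
        k1, k2 = rng.normal(size=4), rng.normal(size=4)
        gamma = 0.7
        Q = Tensor(q[None, None, None, :])
        K = Tensor(np.stack([k1, k2])[None, None])
        V = Tensor(np.eye(2, 4)[None, None])
        bias = Tensor(np.array([[[[gamma * 1.0, gamma * 0.0]]]]))
        _, w = scaled_dot_attention(Q, K, V, 4, bias=bias)
        logits = np.array([q @ k1 / 2.0 + gamma, q @ k2 / 2.0])
        expect = np.exp(logits - logits.max())
        expect /= expect.sum()
        assert np.allclose(w.data[0, 0, 0], expect)

    def test_masked_keys_get_exactly_zero_weight(self, rng):
        Q = Tensor(rng.normal(size=(1, 1, 4, 4)))
        K = Tensor(rng.normal(size=(1, 1, 4, 4)))
        V = Tensor(rng.normal(size=(1, 1, 4, 4)))
        mask = np.array([True, True, False, True])[None, None, None, :]
        _, w = scaled_dot_attention(Q, K, V, 4, key_mask=mask)
        assert np.all(w.data[..., 2] == 0.0)
        assert np.allclose(w.data.sum(axis=-1), 1.0)

    def test_all_keys_masked_degenerates_to_self_attention(self, rng):
        Q = Tensor(rng.normal(size=(1, 1, 3, 4)))
        K = Tensor(rng.normal(size=(1, 1, 3, 4)))
        V = Tensor(rng.normal(size=(1, 1, 3, 4)))
        mask = np.zeros((1, 1, 1, 3), dtype=bool)
        _, w = scaled_dot_attention(Q, K, V, 4, key_mask=mask)
        assert np.allclose(w.data[0, 0], np.eye(3))

    def test_gate_multiplies_output_by_sigmoid(self, rng):
        Q = Tensor(rng.normal(size=(1, 1, 3, 4)))
        K = Tensor(rng.normal(size=(1, 1, 3, 4)))
        V = Tensor(rng.normal(size=(1, 1, 3, 4)))
        G = Tensor(np.full((1, 1, 3, 4), -20.0))
        out, _ = scaled_dot_attention(Q, K, V, 4, gate=G)
        assert np.abs(out.data).max() < 1e-6


class TestEmbeddingTransformer:
    def test_shape_preserved_at_full_resolution(self, rng):
        cfg = ModelConfig()
        emb = EmbeddingTransformer(cfg, 400, np.random.default_rng(0))
        x = Tensor(rng.normal(size=(1, 400, 7)))
        out, w = emb(x, collect=True)
        assert out.shape == (1, 400, 128)
        assert w.shape == (1, 2, 400, 400)
        assert np.abs(w.sum(axis=-1) - 1.0).max() < 1e-5

    def test_deterministic_for_identical_inputs(self, rng):
        cfg = ModelConfig.scaled_down()
        emb = EmbeddingTransformer(cfg, 40, np.random.default_rng(0))
        x = rng.normal(size=(1, 40, 7))
        out1, _ = emb(Tensor(x.copy()))
        out2, _ = emb(Tensor(x.copy()))
        np.testing.assert_array_equal(out1.data, out2.data)

    def test_wrong_bin_count_rejected(self, rng):
        cfg = ModelConfig.scaled_down()
        emb = EmbeddingTransformer(cfg, 40, np.random.default_rng(0))
        with pytest.raises(InputError):
            emb(Tensor(rng.normal(size=(1, 39, 7))))


class TestPairwiseTransformer:
    def test_fully_padded_pcre_is_fixed_transform_of_promoter(self, rng):
        cfg = ModelConfig.scaled_down()
        pair = PairwiseTransformer(cfg, 40, np.random.default_rng(1))
        x_emb = rng.normal(size=(1, 40, 32))
        zeros = Tensor(np.zeros((1, 40, 7)))
        out1, _ = pair(Tensor(x_emb.copy()), zeros)
        out2, _ = pair(Tensor(x_emb.copy()), Tensor(np.zeros((1, 40, 7))))
        np.testing.assert_array_equal(out1.data, out2.data)
        assert out1.shape == (1, 40, 32)

    def test_cross_attention_rows_sum_to_one(self, rng):
        cfg = ModelConfig.scaled_down()
        pair = PairwiseTransformer(cfg, 40, np.random.default_rng(1))
        out, maps = pair(
            Tensor(rng.normal(size=(2, 40, 32))),
            Tensor(rng.normal(size=(2, 40, 7))),
            collect=True,
        )
        assert len(maps) == cfg.n_layers_pair
        for w in maps:
            assert np.abs(w.sum(axis=-1) - 1.0).max() < 1e-5

    def test_bin_count_mismatch_rejected(self, rng):
        cfg = ModelConfig.scaled_down()
        pair = PairwiseTransformer(cfg, 40, np.random.default_rng(1))
        with pytest.raises(InputError):
            pair(Tensor(rng.normal(size=(1, 40, 32))), Tensor(rng.normal(size=(1, 20, 7))))


def reg_toy(rng, n_pcres=3, i_max=3, d=32, seed=2, **cfg_kw):
    cfg = ModelConfig.scaled_down(i_max=i_max, **cfg_kw)
    reg = RegulationTransformer(cfg, np.random.default_rng(seed))
    x = rng.normal(size=(1, i_max + 1, d))
    f = np.abs(rng.normal(size=(1, i_max))) + 0.5
    pad = np.ones((1, i_max + 1), dtype=bool)
    pad[0, 1 + n_pcres :] = False
    f[0, n_pcres:] = 0.0
    return cfg, reg, x, f, pad


class TestRegulationTransformer:
    def test_permutation_invariance_of_promoter_row(self, rng):
        import itertools

        cfg, reg, x, f, pad = reg_toy(rng)
        ref, _ = reg(Tensor(x.copy()), f, pad)
        ref_row0 = ref.data[0, 0]
        for perm in itertools.permutations(range(3)):
            p = np.array(perm)
            xp = x.copy()
            xp[0, 1:4] = x[0, 1:4][p]
            fp = f.copy()
            fp[0, :3] = f[0, :3][p]
            out, _ = reg(Tensor(xp), fp, pad)
            assert np.abs(out.data[0, 0] - ref_row0).max() < 1e-5

    def test_gamma_zero_removes_frequency_dependence(self, rng):
        cfg, reg, x, f, pad = reg_toy(rng)
        for layer in reg.layers:
            layer.gamma.data = np.array(0.0)
        out1, _ = reg(Tensor(x.copy()), f, pad)
        out2, _ = reg(Tensor(x.copy()), f * 3.7, pad)
        np.testing.assert_array_equal(out1.data, out2.data)

    def test_near_zero_gate_reduces_attention_sublayer_to_residual(self, rng):
        cfg = ModelConfig.scaled_down()
        layer = RegulationLayer(cfg, np.random.default_rng(3))
        x = Tensor(rng.normal(size=(1, 9, 32)))
        pad = np.ones((1, 9), dtype=bool)
        out, _ = layer(x, None, pad[:, None, None, :], gate_override=-20.0)
        # with sigma(gate) ~ 0 the gated attention adds ~nothing: the layer
        # output equals the pure residual path through the same norms/FFN
        z = layer.ln1(Tensor(x.data.copy()))
        ref = layer.ln2(z + layer.ffn(z))
        assert np.abs(out.data - ref.data).max() < 1e-4

    def test_bias_monotone_in_frequency(self, rng):
        # with gamma > 0, raising f_j strictly raises the promoter row's
        # attention weight on column j in the first layer
        cfg, reg, x, f, pad = reg_toy(rng)
        _, maps1 = reg(Tensor(x.copy()), f, pad, collect=True)
        f2 = f.copy()
        f2[0, 1] += 1.0
        _, maps2 = reg(Tensor(x.copy()), f2, pad, collect=True)
        w1 = maps1[0][0, :, 0, 2]  # heads, promoter row, column of pCRE 1
        w2 = maps2[0][0, :, 0, 2]
        assert np.all(w2 > w1)

    def test_padded_rows_receive_zero_attention(self, rng):
        cfg, reg, x, f, pad = reg_toy(rng, n_pcres=1)
        _, maps = reg(Tensor(x.copy()), f, pad, collect=True)
        for w in maps:
            assert np.all(w[0, :, :, 2:] == 0.0)
            assert np.abs(w.sum(axis=-1) - 1.0).max() < 1e-5

    def test_negative_frequencies_rejected(self, rng):
        cfg, reg, x, f, pad = reg_toy(rng)
        with pytest.raises(InputError):
            reg(Tensor(x), -f, pad)


class TestModelConfig:
    def test_printed_dimension_defaults(self):
        cfg = ModelConfig()
        assert (cfg.d_model, cfg.d_head_emb, cfg.n_heads_emb) == (128, 64, 2)
        assert (cfg.n_layers_pair, cfg.ffn_pair) == (2, 256)
        assert (cfg.n_layers_reg, cfg.d_head_reg) == (6, 32)
        assert (cfg.i_max, cfg.head_hidden) == (8, 128)
        assert cfg.resolutions == (100, 500, 2000)
        assert [cfg.n_bins(r) for r in cfg.resolutions] == [400, 80, 20]

    def test_head_width_consistency_enforced(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(n_heads_emb=3, d_head_emb=64)
        with pytest.raises(ConfigurationError):
            ModelConfig(d_head_reg=48)

    def test_unknown_task_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(task="rank")


class TestChromoformer:
    def batch_from(self, dataset, n=3):
        return collate(dataset.examples[:n], dataset.config.resolutions)

    def test_clf_emits_two_logits_and_reg_one_scalar(self, toy_dataset):
        batch = self.batch_from(toy_dataset)
        clf = Chromoformer(ModelConfig.scaled_down(seed=0, task="clf"))
        assert clf(batch).prediction.shape == (3, 2)
        reg = Chromoformer(ModelConfig.scaled_down(seed=0, task="reg"))
        assert reg(batch).prediction.shape == (3, 1)

    def test_fixed_seed_and_input_reproduce_bitwise(self, toy_dataset):
        batch = self.batch_from(toy_dataset)
        m1 = Chromoformer(ModelConfig.scaled_down(seed=5))
        m2 = Chromoformer(ModelConfig.scaled_down(seed=5))
        np.testing.assert_array_equal(m1(batch).prediction.data, m2(batch).prediction.data)

    def test_zero_interaction_gene_ignores_pcre_content(self, toy_dataset):
        ex = next(e for e in toy_dataset.examples if e.n_interactions == 0)
        model = Chromoformer(ModelConfig.scaled_down(seed=0))
        batch = collate([ex], toy_dataset.config.resolutions)
        p1 = model(batch).prediction.data.copy()
        batch2 = collate([ex], toy_dataset.config.resolutions)
        for r in batch2["pcres"]:
            batch2["pcres"][r] = batch2["pcres"][r] + 5.0  # garbage in masked slots
        p2 = model(batch2).prediction.data
        np.testing.assert_array_equal(p1, p2)

    def test_embedding_only_shares_embedding_transformer_outputs(self, toy_dataset):
        batch = self.batch_from(toy_dataset)
        full = Chromoformer(ModelConfig.scaled_down(seed=9))
        embo = Chromoformer(ModelConfig.scaled_down(seed=9, embedding_only=True))
        # align the Embedding transformer weights, then X_emb must agree
        state = {k: v for k, v in full.state_dict().items() if k.startswith("emb.")}
        partial = embo.state_dict()
        partial.update(state)
        embo.load_state_dict(partial)
        out_full = full(batch)
        out_embo = embo(batch)
        for r in full.config.resolutions:
            np.testing.assert_array_equal(
                out_full.bundle["resolutions"][r]["prom_vec"],
                out_embo.bundle["resolutions"][r]["prom_vec"],
            )

    def test_channel_count_mismatch_rejected(self, toy_dataset):
        batch = self.batch_from(toy_dataset)
        model = Chromoformer(ModelConfig.scaled_down(seed=0, channels=("H3K4me3",) * 1))
        with pytest.raises(InputError):
            model(batch)

    def test_checkpoint_round_trip(self, toy_dataset, tmp_path):
        batch = self.batch_from(toy_dataset)
        model = Chromoformer(ModelConfig.scaled_down(seed=4))
        ref = model(batch).prediction.data.copy()
        save_checkpoint(model, tmp_path / "m.npz", extra={"window": 40_000})
        loaded, extra = load_checkpoint(tmp_path / "m.npz")
        assert extra["window"] == 40_000
        np.testing.assert_array_equal(loaded(batch).prediction.data, ref)


class TestChromoformerDiff:
    def test_siamese_symmetry_and_arity(self, toy_dataset):
        res = toy_dataset.config.resolutions
        a = collate(toy_dataset.examples[:2], res)
        b = collate(toy_dataset.examples[2:4], res)
        model = ChromoformerDiff(ModelConfig.scaled_down(seed=1, task="diff"))
        fc, aux_a, aux_b = model(a, b)
        assert fc.shape == (2, 1) and aux_a.shape == (2, 1) and aux_b.shape == (2, 1)
        fc2, aux_a2, aux_b2 = model(b, a)
        np.testing.assert_array_equal(aux_a.data, aux_b2.data)
        np.testing.assert_array_equal(aux_b.data, aux_a2.data)

    def test_identical_inputs_give_equal_auxiliaries(self, toy_dataset):
        res = toy_dataset.config.resolutions
        a = collate(toy_dataset.examples[:2], res)
        model = ChromoformerDiff(ModelConfig.scaled_down(seed=1, task="diff"))
        _, aux_a, aux_b = model(a, a)
        np.testing.assert_array_equal(aux_a.data, aux_b.data)

    def test_requires_diff_task(self):
        with pytest.raises(ConfigurationError):
            ChromoformerDiff(ModelConfig.scaled_down(seed=1, task="clf"))
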