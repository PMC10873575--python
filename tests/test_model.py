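"""Architecture contracts: attention, branch encoders, fusion, classifier."""

import math

import numpy as np
import pytest

from nanocon import ModelConfig, NanoConModel, prepare_batch, self_attention
from nanocon.model import ABLATION_FLAGS
from nanocon._autograd import Tensor

from conftest import make_instance


def attention_oracle(x, w_q, w_k, w_v):
    """Three-loop scaled dot-product attention on plain Python floats."""
    n, d_model = len(x), len(x[0])
    d_k = len(w_q[0])

    def matmul(a, b):
        return [[sum(a[i][k] * b[k][j] for k in range(len(b)))
                 for j in range(len(b[0]))] for i in range(len(a))]

    q, k, v = matmul(x, w_q), matmul(x, w_k), matmul(x, w_v)
    out = []
    for i in range(n):
        scores = [sum(q[i][t] * k[j][t] for t in range(d_k)) / math.sqrt(d_k)
                  for j in range(n)]
        m = max(scores)
        exps = [math.exp(s - m) for s in scores]
        z = sum(exps)
        weights = [e / z for e in exps]
        out.append([sum(weights[j] * v[j][t] for j in range(n))
                    for t in range(len(v[0]))])
    return np.array(out)


class TestSelfAttention:
    def test_attention_rows_sum_to_one(self, rng):
        x = rng.normal(size=(9, 8))
        w = [rng.normal(size=(8, 8)) for _ in range(3)]
        _, weights = self_attention(x, *w, return_weights=True)
        np.testing.assert_allclose(weights.data.sum(axis=-1), np.ones(9))

    def test_zero_projections_give_uniform_attention(self, rng):
        x = rng.normal(size=(9, 8))
        zeros = np.zeros((8, 8))
        w_v = rng.normal(size=(8, 8))
        out, weights = self_attention(x, zeros, zeros, w_v, return_weights=True)
        np.testing.assert_allclose(weights.data, np.full((9, 9), 1 / 9))
        v = x @ w_v
        np.testing.assert_allclose(out.data,
                                   np.tile(v.mean(axis=0), (9, 1)))

    def test_matches_three_loop_oracle(self, rng):
        x = rng.normal(size=(2, 4))
        w_q, w_k, w_v = (rng.normal(size=(4, 4)) for _ in range(3))
        out = self_attention(x, w_q, w_k, w_v)
        expected = attention_oracle(x.tolist(), w_q.tolist(), w_k.tolist(),
                                    w_v.tolist())
        np.testing.assert_allclose(out.data, expected, atol=1e-12)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="dim mismatch"):
            self_attention(rng.normal(size=(9, 8)),
                           *(rng.normal(size=(4, 4)) for _ in range(3)))


@pytest.fixture(scope="module")
def batch():
    instances = [make_instance(read_id=f"r{i}", pos=10 * i,
                               motif="ACGTAC" + "C" + "TACGTA"[:6])
                 for i in range(4)]
    return prepare_batch(instances)


@pytest.fixture(scope="module")
def model():
    return NanoConModel(ModelConfig(embed_dim=16, n_transformer_layers=1,
                                    n_heads=2, signal_encoder_dims=(16, 16),
                                    gru_hidden=8), seed=0)


class TestEncoders:
    def test_sequence_output_shape(self, model, batch):
        out = model.encode_sequence(batch["tokens"])
        assert out.shape == (4, 9, 16)

    def test_batch_equivariance(self, model, rng):
        tokens = rng.integers(0, 1024, size=(5, 9))
        out = model.encode_sequence(tokens).data
        perm = rng.permutation(5)
        out_perm = model.encode_sequence(tokens[perm]).data
        np.testing.assert_allclose(out_perm, out[perm], atol=1e-12)

    def test_mask_sequence_zeroes_branch(self, batch):
        masked = NanoConModel(
            ModelConfig(embed_dim=16, n_heads=2, gru_hidden=8,
                        ablation_flags={"mask_sequence"}), seed=0)
        out = masked.encode_sequence(batch["tokens"])
        np.testing.assert_array_equal(out.data, 0.0)
        assert out.shape == (4, 9, 16)

    def test_signal_output_dim_and_determinism(self, model):
        zeros = np.zeros((2, 13))
        a = model.encode_signal(zeros, zeros, zeros).data
        b = model.encode_signal(zeros, zeros, zeros).data
        assert a.shape == (2, 16)  # last entry of signal_encoder_dims
        np.testing.assert_array_equal(a, b)

    def test_mask_means_zeroes_track(self, rng):
        cfg = ModelConfig(embed_dim=16, n_heads=2, gru_hidden=8)
        base = NanoConModel(cfg, seed=0)
        masked = NanoConModel(cfg.with_flags("mask_means"), seed=0)
        means = rng.normal(size=(3, 13))
        stds, lens = np.abs(rng.normal(size=(3, 13))), np.ones((3, 13))
        np.testing.assert_array_equal(
            masked.encode_signal(means, stds, lens).data,
            masked.encode_signal(np.zeros((3, 13)), stds, lens).data)
        assert not np.array_equal(
            base.encode_signal(means, stds, lens).data,
            masked.encode_signal(means, stds, lens).data)

    def test_non_finite_signal_raises(self, model):
        bad = np.full((1, 13), np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            model.encode_signal(bad, np.ones((1, 13)), np.ones((1, 13)))


class TestFusionAndClassifier:
    def test_repr_dim_is_twice_gru_hidden(self, model, batch):
        _, reprs = model.forward(batch)
        assert reprs.shape == (4, 2 * 8)
        assert model.config.repr_dim == 16

    def test_no_gru_variant_repr_dim(self, batch):
        cfg = ModelConfig(embed_dim=16, n_heads=2, gru_hidden=8,
                          ablation_flags={"no_gru"})
        m = NanoConModel(cfg, seed=0)
        _, reprs = m.forward(batch)
        assert reprs.shape == (4, cfg.repr_dim)
        assert "encoder.fuse_fc.w" in m.params
        assert not any(k.startswith("encoder.gru") for k in m.params)

    def test_forward_deterministic(self, model, batch):
        p1, r1 = model.forward(batch)
        p2, r2 = model.forward(batch)
        np.testing.assert_array_equal(p1.data, p2.data)
        np.testing.assert_array_equal(r1.data, r2.data)

    def test_probabilities_sum_to_one(self, model, rng):
        reprs = Tensor(rng.normal(size=(6, 16)))
        probs = model.classify(reprs).data
        np.testing.assert_allclose(probs.sum(axis=1), np.ones(6))
        assert (probs >= 0).all()

    def test_softmax_monotone_in_logit_shift(self, model, rng):
        # shifting the class-1 logit up by a constant raises P(class 1)
        reprs = rng.normal(size=(4, 16))
        probs = model.classify(Tensor(reprs)).data[:, 1]
        model.params["classifier.1.b"].data[1] += 1.0
        shifted = model.classify(Tensor(reprs)).data[:, 1]
        model.params["classifier.1.b"].data[1] -= 1.0
        assert (shifted > probs).all()

    def test_dropout_only_in_training_path(self, model, batch):
        rng_a = np.random.default_rng(0)
        ctx = model.encode_sequence(batch["tokens"])
        sig = model.encode_signal(batch["means"], batch["stds"], batch["lens"])
        train_run = model.fuse(ctx, sig, dropout_rng=rng_a).data
        eval_run = model.fuse(ctx, sig, dropout_rng=None).data
        assert not np.array_equal(train_run, eval_run)
        np.testing.assert_array_equal(
            model.fuse(ctx, sig, dropout_rng=None).data, eval_run)


class TestAblationNonDegeneracy:
    @pytest.mark.parametrize("flag", sorted(ABLATION_FLAGS - {"no_contrast"}))
    def test_each_flag_changes_outputs(self, flag, rng):
        cfg = ModelConfig(embed_dim=16, n_heads=2, gru_hidden=8)
        instances = [make_instance(
            motif="AGCTAG" + "C" + "GATCGA"[:6], read_id=f"r{i}",
            means=rng.normal(size=13), stds=np.abs(rng.normal(size=13)) + 0.1,
            lens=rng.integers(1, 20, size=13)) for i in range(3)]
        batch = prepare_batch(instances)
        base = NanoConModel(cfg, seed=0).forward(batch)[1].data
        variant = NanoConModel(cfg.with_flags(flag), seed=0).forward(batch)[1].data
        assert base.shape == variant.shape
        assert not np.allclose(base, variant)

    def test_unknown_flag_rejected(self):
        with pytest.raises(ValueError, match="unknown ablation"):
            ModelConfig(ablation_flags={"mask_everything"})


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, model, batch):
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = NanoConModel.load(path)
        np.testing.assert_array_equal(loaded.forward(batch)[0].data,
                                      model.forward(batch)[0].data)
        assert loaded.config == model.config

    def test_vocab_mismatch_raises(self, tmp_path, model):
        path = tmp_path / "model.npz"
        model.save(path)
        other_vocab = {k: v for k, v in model.vocab.items()}
        other_vocab["XXXXX"] = len(other_vocab)
        with pytest.raises(ValueError, match="vocabulary mismatch"):
            NanoConModel.load(path, vocab=other_vocab)


def test_embed_dim_must_divide_heads():
    with pytest.raises(ValueError, match="divisible"):
        ModelConfig(embed_dim=10, n_heads=4)
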