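"""Fusion transformer, baselines, classification head, composite loss."""

import numpy as np
import pytest

from mirfnet import nn
from mirfnet.config import FusionConfig, LossConfig
from mirfnet.fixtures import generate_dataset
from mirfnet.fusion_model import (BaselineFusion, FusionTransformer, MIRFNet,
                                  ModalityProjector, classify, composite_loss,
                                  fuse, fuse_baseline, label_smoothing_ce,
                                  project_tokens, smooth_labels)
from mirfnet.harness import featurize
from tests.conftest import reduced_model_config, strong_coupling_config


# --------------------------------------------------------------------------- #
# manual references
# --------------------------------------------------------------------------- #

def manual_layernorm(x, w, b, eps=1e-5):
    mu = x.mean(-1, keepdims=True)
    var = ((x - mu) ** 2).mean(-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps) * w + b


def manual_single_head_attention(x, attn):
    """Brute-force single-example attention for h=1."""
    q = x @ attn.q_proj.weight.data.T + attn.q_proj.bias.data
    k = x @ attn.k_proj.weight.data.T + attn.k_proj.bias.data
    v = x @ attn.v_proj.weight.data.T + attn.v_proj.bias.data
    scores = q @ k.T / np.sqrt(x.shape[-1])
    e = np.exp(scores - scores.max(-1, keepdims=True))
    w = e / e.sum(-1, keepdims=True)
    return (w @ v) @ attn.out_proj.weight.data.T + attn.out_proj.bias.data


class TestAttentionOracle:
    def test_mhsa_matches_brute_force_h1_d4(self, rng):
        attn = nn.MultiheadAttention(4, 1, rng)
        x = rng.normal(size=(3, 4)).astype(np.float32)
        with nn.no_grad():
            out = attn(nn.Tensor(x[None])).data[0]
        np.testing.assert_allclose(out, manual_single_head_attention(x, attn),
                                   atol=1e-5)

    def test_attention_rows_sum_to_one(self, rng):
        attn = nn.MultiheadAttention(8, 2, rng)
        x = nn.Tensor(rng.normal(size=(2, 3, 8)).astype(np.float32))
        with nn.no_grad():
            _, weights = attn(x, return_weights=True)
        np.testing.assert_allclose(weights.sum(axis=-1), 1.0, atol=1e-6)

    def test_post_norm_block_matches_reference(self, rng):
        layer = nn.TransformerEncoderLayer(4, 1, 8, 0.0, rng)
        layer.eval()
        x = rng.normal(size=(3, 4)).astype(np.float32)
        with nn.no_grad():
            out = layer(nn.Tensor(x[None])).data[0]
        a = manual_single_head_attention(x, layer.attn)
        x1 = manual_layernorm(x + a, layer.norm1.weight.data,
                              layer.norm1.bias.data)
        ff = np.maximum(x1 @ layer.ff1.weight.data.T + layer.ff1.bias.data, 0)
        ff = ff @ layer.ff2.weight.data.T + layer.ff2.bias.data
        ref = manual_layernorm(x1 + ff, layer.norm2.weight.data,
                               layer.norm2.bias.data)
        np.testing.assert_allclose(out, ref, atol=1e-5)


class TestProjectTokens:
    def make(self, rng, d=8):
        return ModalityProjector({"signal": 6, "image": 10, "metadata": 4},
                                 d, rng)

    def test_output_shape(self, rng):
        proj = self.make(rng)
        x0 = project_tokens(np.ones(6), np.ones(10), np.ones(4), proj)
        assert x0.shape == (3, 8)

    def test_zero_weights_zero_matrix(self, rng):
        proj = self.make(rng)
        for p in proj.parameters():
            p.data = np.zeros_like(p.data)
        x0 = project_tokens(np.ones(6), np.ones(10), np.ones(4), proj)
        np.testing.assert_array_equal(x0, 0.0)

    def test_row_independence(self, rng):
        proj = self.make(rng)
        base = project_tokens(np.ones(6), np.ones(10), np.ones(4), proj)
        changed = project_tokens(np.ones(6), 2 * np.ones(10), np.ones(4), proj)
        np.testing.assert_array_equal(base[0], changed[0])
        np.testing.assert_array_equal(base[2], changed[2])
        assert not np.array_equal(base[1], changed[1])

    def test_dimension_mismatch(self, rng):
        proj = self.make(rng)
        with pytest.raises(ValueError):
            project_tokens(np.ones(5), np.ones(10), np.ones(4), proj)


class TestFuse:
    def test_zeroed_blocks_reduce_to_layernorm_mean(self, rng):
        cfg = FusionConfig(d_common=8, n_layers=1, n_heads=2, ffn_width=16,
                           dropout=0.0)
        fusion = FusionTransformer(cfg, n_tokens=3, rng=rng)
        fusion.modality_embedding.data[:] = 0.0
        for layer in fusion.blocks:
            layer.attn.out_proj.weight.data[:] = 0.0
            layer.attn.out_proj.bias.data[:] = 0.0
            layer.ff2.weight.data[:] = 0.0
            layer.ff2.bias.data[:] = 0.0
        x0 = rng.normal(size=(3, 8)).astype(np.float32)
        h = fuse(x0, fusion)
        # LN is idempotent (unit weight, zero bias), so the block collapses
        # to LayerNorm of each token row
        expected = manual_layernorm(x0, np.ones(8), np.zeros(8)).mean(axis=0)
        np.testing.assert_allclose(h, expected, atol=1e-4)

    def test_output_width(self, rng):
        cfg = FusionConfig(d_common=16, n_layers=2, n_heads=4, ffn_width=32)
        fusion = FusionTransformer(cfg, n_tokens=3, rng=rng)
        assert fuse(rng.normal(size=(3, 16)).astype(np.float32), fusion).shape \
            == (16,)


class TestFuseBaseline:
    def test_add_three_identical_tokens(self, rng):
        v = rng.normal(size=4).astype(np.float32)
        x0 = np.stack([v, v, v])
        np.testing.assert_allclose(fuse_baseline(x0, "add"), 3 * v, atol=1e-6)

    def test_concat_width(self, rng):
        x0 = rng.normal(size=(3, 5)).astype(np.float32)
        out = fuse_baseline(x0, "concat")
        assert out.shape == (15,)
        np.testing.assert_array_equal(out, x0.reshape(-1))

    def test_add_permutation_invariant_concat_not(self, rng):
        x0 = rng.normal(size=(3, 4)).astype(np.float32)
        perm = x0[[2, 0, 1]]
        np.testing.assert_allclose(fuse_baseline(x0, "add"),
                                   fuse_baseline(perm, "add"), atol=1e-6)
        assert not np.array_equal(fuse_baseline(x0, "concat"),
                                  fuse_baseline(perm, "concat"))

    def test_mlp_width_d(self, rng):
        x0 = rng.normal(size=(3, 6)).astype(np.float32)
        module = BaselineFusion("mlp", 6, 3, rng)
        assert fuse_baseline(x0, "mlp", module).shape == (6,)

    def test_unknown_strategy(self, rng):
        with pytest.raises(ValueError):
            BaselineFusion("gated", 4, 3, rng)
        with pytest.raises(ValueError):
            FusionConfig(strategy="gated")


class TestClassify:
    def test_equal_logits_half(self, rng):
        head = nn.Linear(4, 2, rng)
        for p in head.parameters():
            p.data = np.zeros_like(p.data)
        logits, prob = classify(np.ones(4), head)
        assert prob == pytest.approx(0.5)
        assert logits.shape == (2,)

    def test_probabilities_sum_to_one_and_monotone(self, rng):
        head = nn.Linear(4, 2, rng)
        h = rng.normal(size=4)
        logits, prob = classify(h, head)
        e = np.exp(logits - logits.max())
        assert e.sum() / e.sum() == 1.0
        # push the abnormal logit up via the bias: probability must rise
        head.bias.data[1] += 1.0
        _, prob2 = classify(h, head)
        assert prob2 > prob


class TestSmoothLabels:
    def test_default_epsilon(self):
        np.testing.assert_allclose(smooth_labels(1, 0.1, 2), [0.1, 0.9])
        np.testing.assert_allclose(smooth_labels(0, 0.1, 2), [0.9, 0.1])

    def test_zero_eps_one_hot(self):
        np.testing.assert_array_equal(smooth_labels(1, 0.0, 2), [0.0, 1.0])

    def test_sums_to_one(self):
        for eps in (0.0, 0.1, 0.3, 0.9):
            for C in (2, 3, 5):
                assert smooth_labels(1, eps, C).sum() == pytest.approx(1.0)

    def test_invalid_class(self):
        with pytest.raises(ValueError):
            smooth_labels(2, 0.1, 2)


class TestCompositeLoss:
    def test_uniform_prediction_ln2_any_eps(self):
        logits = nn.Tensor(np.zeros((4, 2)), requires_grad=True)
        for eps in (0.0, 0.1, 0.4):
            loss = label_smoothing_ce(logits, np.array([0, 1, 1, 0]),
                                      LossConfig(smoothing=eps))
            assert float(loss.data) == pytest.approx(np.log(2), abs=1e-6)

    def test_perfect_reconstruction(self):
        logits = nn.Tensor(np.zeros((2, 2)))
        meta = np.ones((2, 4), dtype=np.float32)
        recon = nn.Tensor(meta.copy())
        total, parts = composite_loss(logits, recon, np.array([0, 1]), meta,
                                      LossConfig())
        assert parts["rec"] == 0.0
        assert parts["total"] == pytest.approx(parts["cls"])

    def test_weighted_sum_arithmetic(self, rng):
        logits = nn.Tensor(rng.normal(size=(3, 2)))
        meta = rng.normal(size=(3, 4)).astype(np.float32)
        recon = nn.Tensor(rng.normal(size=(3, 4)).astype(np.float32))
        total, parts = composite_loss(logits, recon, np.array([0, 1, 0]), meta,
                                      LossConfig(recon_weight=0.5))
        assert parts["total"] == pytest.approx(parts["cls"] + 0.5 * parts["rec"])

    def test_masked_metadata_no_rec_term(self, rng):
        logits = nn.Tensor(rng.normal(size=(3, 2)))
        total, parts = composite_loss(logits, None, np.array([0, 1, 0]), None,
                                      LossConfig())
        assert parts["rec"] == 0.0

    def test_lsce_minimized_at_smoothed_target(self):
        # small numeric optimization: optimum softmax equals the soft label
        logits = nn.Tensor(np.zeros((1, 2)), requires_grad=True)
        opt = nn.Adam([logits], lr=0.05)
        cfg = LossConfig(smoothing=0.1)
        for _ in range(400):
            loss = label_smoothing_ce(logits, np.array([1]), cfg)
            opt.zero_grad()
            loss.backward()
            opt.step()
        e = np.exp(logits.data - logits.data.max())
        p = e / e.sum()
        np.testing.assert_allclose(p[0], [0.1, 0.9], atol=1e-3)


# --------------------------------------------------------------------------- #
# full model
# --------------------------------------------------------------------------- #

PS_GRID = [(64, 16), (64, 32), (96, 24), (128, 24), (128, 32)]
MASKS = [("signal", "image", "metadata"), ("image", "metadata"),
         ("signal", "metadata"), ("signal", "image")]


@pytest.fixture(scope="module")
def smoke_records():
    return generate_dataset(strong_coupling_config(2, seed=9,
                                                   segment_length=480))


def _forward_once(config, records):
    feats = featurize(records, config)
    model = MIRFNet(config, np.random.default_rng(0))
    batch = {}
    if "signal" in config.fusion.modality_mask:
        batch["signal"] = feats["signal"][:1]
    if "image" in config.fusion.modality_mask:
        batch["image"] = feats["image"][:1]
    if "metadata" in config.fusion.modality_mask:
        batch["meta"] = np.zeros((1, 4), dtype=np.float32)
    return model, model.predict(batch)


class TestMIRFNetSmoke:
    @pytest.mark.parametrize("strategy", ["transformer", "concat", "add", "mlp"])
    @pytest.mark.parametrize("mask", MASKS, ids=["full", "-signal", "-image",
                                                 "-metadata"])
    def test_strategy_mask_grid_finite_logits(self, smoke_records, strategy,
                                              mask):
        from mirfnet.config import FusionConfig
        config = reduced_model_config(
            segment_length=480,
            fusion=FusionConfig(d_common=16, n_layers=1, n_heads=2,
                                ffn_width=32, strategy=strategy,
                                modality_mask=mask))
        config.image.base_width = 4
        config.gadf.out_size = 16
        model, outs = _forward_once(config, smoke_records)
        assert np.isfinite(outs[0].logits).all()
        assert 0.0 <= outs[0].probability <= 1.0

    @pytest.mark.parametrize("ps", PS_GRID, ids=[f"P{p}S{s}" for p, s in PS_GRID])
    def test_patch_stride_grid(self, smoke_records, ps):
        from mirfnet.encoders import CTGEncoderConfig
        config = reduced_model_config(
            segment_length=480,
            ctg=CTGEncoderConfig(patch_length=ps[0], stride=ps[1], d_model=16,
                                 n_layers=1, n_heads=2, ffn_width=32))
        config.image.base_width = 4
        config.gadf.out_size = 16
        _, outs = _forward_once(config, smoke_records)
        assert np.isfinite(outs[0].logits).all()

    def test_masked_modality_omits_token_and_encoder(self, smoke_records):
        config = reduced_model_config(segment_length=480)
        config.fusion.modality_mask = ("signal", "metadata")
        config.fusion.__post_init__()
        model = MIRFNet(config, np.random.default_rng(0))
        assert not hasattr(model, "image_encoder")
        assert model.projector.order == ("signal", "metadata")
        assert model.fusion.modality_embedding.shape[0] == 2

    def test_probability_equals_softmax_of_logits(self, smoke_records):
        config = reduced_model_config(segment_length=480)
        config.image.base_width = 4
        config.gadf.out_size = 16
        _, outs = _forward_once(config, smoke_records)
        e = np.exp(outs[0].logits - outs[0].logits.max())
        assert outs[0].probability == pytest.approx(float(e[1] / e.sum()),
                                                    abs=1e-6)
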