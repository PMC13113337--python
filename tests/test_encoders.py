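"""Modality encoders: patching, CTG Transformer, residual net, metadata."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirfnet import nn
from mirfnet.encoders import (CTGEncoder, CTGEncoderConfig, ImageEncoderConfig,
                              MetadataAutoencoder, MetadataEncoderConfig,
                              ResNetEncoder, decode_metadata, encode_ctg,
                              encode_image, encode_metadata,
                              fit_metadata_stats, instance_normalize,
                              patch_count, patchify, standardize_metadata)
from mirfnet.gadf import GADFImage
from mirfnet.records import MaternalMetadata


class TestInstanceNormalize:
    def test_three_point_example(self):
        out = instance_normalize(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out, [-1.2247, 0.0, 1.2247], atol=1e-3)

    def test_constant_input_zeros(self):
        np.testing.assert_allclose(instance_normalize(np.full(10, 5.0)), 0.0)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=200)
        # exact up to the eps guard's second-order effect
        np.testing.assert_allclose(instance_normalize(3.0 * x + 7.0),
                                   instance_normalize(x), atol=1e-4)

    def test_output_moments(self, rng):
        out = instance_normalize(rng.normal(130, 9, 500))
        assert abs(out.mean()) < 1e-8
        assert abs(out.std() - 1.0) < 1e-4

    def test_idempotent(self, rng):
        x = instance_normalize(rng.normal(size=300))
        np.testing.assert_allclose(instance_normalize(x), x, atol=1e-4)


class TestPatchify:
    def test_small_example(self):
        out = patchify(np.arange(8.0), P=4, S=2)
        assert out.shape == (3, 4)
        np.testing.assert_array_equal(out[0], [0, 1, 2, 3])
        np.testing.assert_array_equal(out[2], [4, 5, 6, 7])

    def test_full_scale_count(self):
        assert patch_count(7200, 64, 32) == 224

    def test_zero_padding_tail(self):
        out = patchify(np.arange(1.0, 10.0), P=4, S=2)
        assert out.shape == (4, 4)
        np.testing.assert_array_equal(out[-1], [7, 8, 9, 0])

    def test_p_greater_than_l_error(self):
        with pytest.raises(ValueError):
            patchify(np.arange(5.0), P=6, S=2)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(2, 300), st.integers(1, 50), st.integers(1, 50))
    def test_count_matches_enumerator(self, L, P, S):
        if P > L or S > P:
            return
        # brute-force enumerator: slide in steps of S until the window start
        # passes the last sample needing coverage
        starts = []
        s = 0
        while True:
            starts.append(s)
            if s + P >= L:
                break
            s += S
        out = patchify(np.arange(float(L)), P, S)
        assert out.shape == (len(starts), P)
        assert patch_count(L, P, S) == len(starts)


@pytest.fixture(scope="module")
def ctg_encoder():
    cfg = CTGEncoderConfig(patch_length=16, stride=8, d_model=16, n_layers=1,
                           n_heads=2, ffn_width=32, dropout=0.0)
    return CTGEncoder(series_length=128, config=cfg,
                      rng=np.random.default_rng(3))


class TestCTGEncoder:
    def test_output_length_two_d_model(self, ctg_encoder, rng):
        fhr, uc = rng.normal(130, 5, 128), rng.normal(20, 5, 128)
        g = encode_ctg(fhr, uc, ctg_encoder)
        assert g.shape == (2 * ctg_encoder.config.d_model,)

    def test_channel_independence(self, ctg_encoder, rng):
        fhr = rng.normal(130, 5, 128)
        uc1, uc2 = rng.normal(20, 5, 128), rng.normal(40, 9, 128)
        d = ctg_encoder.config.d_model
        g1 = encode_ctg(fhr, uc1, ctg_encoder)
        g2 = encode_ctg(fhr, uc2, ctg_encoder)
        np.testing.assert_array_equal(g1[:d], g2[:d])
        assert not np.array_equal(g1[d:], g2[d:])

    def test_weight_sharing_identical_channels(self, ctg_encoder, rng):
        x = rng.normal(130, 5, 128)
        g = encode_ctg(x, x, ctg_encoder)
        d = ctg_encoder.config.d_model
        np.testing.assert_array_equal(g[:d], g[d:])

    def test_channel_length_mismatch(self, ctg_encoder, rng):
        with pytest.raises(ValueError):
            ctg_encoder.prepare(rng.normal(size=128), rng.normal(size=64))

    def test_d_model_head_divisibility(self):
        with pytest.raises(ValueError):
            CTGEncoderConfig(d_model=30, n_heads=4)


class TestResNetEncoder:
    def test_out_dims_per_depth(self):
        for depth, expected in ((50, 2048), (101, 2048), (152, 2048),
                                (18, 512), (10, 512)):
            assert ImageEncoderConfig(depth=depth, pretrained=False).out_dim \
                == expected

    def test_depth_101_forward_2048(self, rng):
        # the one full-size forward in the suite (slow: ~40 M parameters)
        enc = ResNetEncoder(ImageEncoderConfig(depth=101, pretrained=False),
                            rng)
        img = GADFImage(np.clip(rng.normal(size=(224, 224)), -1, 1)
                        .astype(np.float32), 7200)
        v1 = encode_image(img, enc, expected_size=224)
        assert v1.shape == (2048,)
        v2 = encode_image(img, enc, expected_size=224)
        np.testing.assert_array_equal(v1, v2)  # deterministic in eval mode

    def test_wrong_spatial_size_rejected(self, rng):
        enc = ResNetEncoder(ImageEncoderConfig(depth=10, base_width=8,
                                               small_input=True,
                                               pretrained=False), rng)
        img = GADFImage(np.zeros((16, 16), dtype=np.float32), 100)
        with pytest.raises(ValueError):
            encode_image(img, enc, expected_size=32)

    def test_partial_fine_tune_gradient_partition(self, rng):
        enc = ResNetEncoder(ImageEncoderConfig(depth=10, base_width=8,
                                               small_input=True,
                                               pretrained=False,
                                               fine_tune="partial"), rng)
        trainable = {n for n, p in enc.named_parameters() if p.requires_grad}
        frozen = {n for n, p in enc.named_parameters() if not p.requires_grad}
        assert trainable and frozen
        assert all(n.startswith(("stage3", "stage4")) for n in trainable)
        # dummy step: gradients reach only the two deepest stages
        x = nn.Tensor(rng.normal(size=(2, 3, 16, 16)).astype(np.float32))
        out = enc(x)
        (out ** 2).sum().backward()
        for name, p in enc.named_parameters():
            if name in frozen:
                assert p.grad is None, name
            else:
                assert p.grad is not None, name

    def test_pretrained_fallback_warns(self, rng):
        with pytest.warns(UserWarning, match="random initialization"):
            ResNetEncoder(ImageEncoderConfig(depth=10, base_width=8,
                                             small_input=True,
                                             pretrained=True), rng)

    def test_unsupported_depth(self):
        with pytest.raises(ValueError):
            ImageEncoderConfig(depth=34)


class TestMetadataStats:
    def _records(self, ages):
        return [MaternalMetadata(age=a, gravidity=1.0, parity=0.0, diabetes=0)
                for a in ages]

    def test_mean_and_sample_sd(self):
        stats = fit_metadata_stats(self._records([20.0, 30.0, 40.0]))
        assert stats.means["age"] == 30.0
        assert abs(stats.sds["age"] - 10.0) < 1e-12  # sample sd (n-1)

    def test_missing_excluded_from_imputation_mean(self):
        metas = [MaternalMetadata(age=30, gravidity=2.0, parity=0, diabetes=0),
                 MaternalMetadata(age=30, gravidity=None, parity=0, diabetes=0),
                 MaternalMetadata(age=30, gravidity=4.0, parity=0, diabetes=0)]
        stats = fit_metadata_stats(metas)
        assert stats.means["gravidity"] == 3.0

    def test_zero_variance_guard(self):
        with pytest.warns(UserWarning, match="zero variance"):
            stats = fit_metadata_stats(self._records([25.0, 25.0]))
        assert stats.sds["age"] == 1.0

    def test_needs_two_records(self):
        with pytest.raises(ValueError):
            fit_metadata_stats(self._records([25.0]))


class TestStandardize:
    def test_mean_age_zscores_to_zero(self):
        stats = fit_metadata_stats(
            [MaternalMetadata(age=a, gravidity=1, parity=0, diabetes=0)
             for a in (20.0, 30.0, 40.0)])
        vec = standardize_metadata(
            MaternalMetadata(age=30.0, gravidity=1.0, parity=0.0, diabetes=1),
            stats)
        assert vec[0] == 0.0

    def test_diabetes_passthrough(self):
        stats = fit_metadata_stats(
            [MaternalMetadata(age=a, gravidity=1, parity=0, diabetes=0)
             for a in (20.0, 30.0)])
        for d in (0, 1):
            vec = standardize_metadata(
                MaternalMetadata(age=25.0, gravidity=1.0, parity=0.0,
                                 diabetes=d), stats)
            assert vec[3] == float(d)

    def test_missing_gravidity_standardizes_to_zero(self):
        stats = fit_metadata_stats(
            [MaternalMetadata(age=25, gravidity=g, parity=0, diabetes=0)
             for g in (1.0, 3.0)])
        vec = standardize_metadata(
            MaternalMetadata(age=25.0, gravidity=None, parity=0.0, diabetes=0),
            stats)
        assert vec[1] == 0.0


class TestMetadataAutoencoder:
    def test_shapes(self, rng):
        ae = MetadataAutoencoder(MetadataEncoderConfig(), rng)
        z = encode_metadata(np.zeros(4), ae)
        assert z.shape == (32,)
        assert decode_metadata(z, ae).shape == (4,)

    def test_zero_weights_give_zero(self, rng):
        ae = MetadataAutoencoder(MetadataEncoderConfig(), rng)
        for p in ae.parameters():
            p.data = np.zeros_like(p.data)
        assert np.all(encode_metadata(np.ones(4), ae) == 0.0)
        assert np.all(decode_metadata(np.ones(32), ae) == 0.0)

    def test_overfits_16_fixed_vectors(self, rng):
        # threshold frozen after the first seeded run (MSE ~1e-5 at 400 steps)
        ae = MetadataAutoencoder(MetadataEncoderConfig(), np.random.default_rng(0))
        X = np.random.default_rng(1).normal(size=(16, 4)).astype(np.float32)
        opt = nn.Adam(ae.parameters(), lr=1e-3)
        for _ in range(400):
            x = nn.Tensor(X)
            _, xhat = ae(x)
            diff = xhat - x
            loss = (diff * diff).sum(axis=-1).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert float(loss.data) < 0.05
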