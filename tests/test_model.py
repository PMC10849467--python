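"""Patch slicing, masking, encoding, heads, missing-sensor substitution,
parameter counting, checkpointing — including the dense-math attention oracle."""

import numpy as np
import pytest

from imugrf.errors import ConfigError, ValidationError
from imugrf.layout import CANONICAL_SENSORS
from imugrf.model import (
    ModelConfig,
    PatchMaskedTransformer,
    count_parameters,
    sample_mask,
    slice_patches,
    unslice_patches,
)
from imugrf.nn.autograd import Tensor


class TestConfig:
    def test_indivisible_patch_length_rejected(self):
        with pytest.raises(ConfigError):
            ModelConfig(patch_length=3)

    def test_embed_head_divisibility(self):
        with pytest.raises(ConfigError):
            ModelConfig(embed_dim=100, n_heads=8)


class TestPatches:
    @pytest.mark.parametrize("patch_length,n_patches,patch_dim", [
        (8, 16, 384), (1, 128, 48), (4, 32, 192),
    ])
    def test_shapes(self, rng, patch_length, n_patches, patch_dim):
        w = rng.normal(size=(128, 48))
        p = slice_patches(w, patch_length)
        assert p.shape == (n_patches, patch_dim)

    def test_slice_unslice_identity(self, rng):
        w = rng.normal(size=(5, 128, 48))
        for L in (1, 2, 4, 8):
            assert np.abs(unslice_patches(slice_patches(w, L), L) - w).max() == 0

    def test_patch_rows_are_contiguous(self, rng):
        w = rng.normal(size=(128, 48))
        p = slice_patches(w, 8)
        np.testing.assert_array_equal(p[3], w[24:32].ravel())


class TestMaskSampling:
    @pytest.mark.parametrize("n,ratio,expected", [
        (16, 0.125, 2), (128, 0.0625, 8), (128, 0.125, 16), (16, 0.0625, 1),
    ])
    def test_mask_counts(self, n, ratio, expected):
        idx = sample_mask(n, ratio, 0)
        assert len(idx) == expected
        assert len(set(idx)) == expected and idx.max() < n

    def test_seeded_determinism(self):
        np.testing.assert_array_equal(sample_mask(64, 0.25, 7),
                                      sample_mask(64, 0.25, 7))

    def test_zero_mask_count_rejected(self):
        with pytest.raises(ConfigError):
            sample_mask(4, 0.1, 0)


class TestApplyMask:
    def setup_method(self):
        self.cfg = ModelConfig.tiny()
        self.model = PatchMaskedTransformer(self.cfg, rng=0)

    def test_empty_mask_is_identity(self, rng):
        p = rng.normal(size=(32, self.cfg.patch_dim))
        out = self.model.apply_mask(p, np.zeros(32, dtype=bool))
        np.testing.assert_array_equal(out.data, p)

    def test_full_mask_saturates(self, rng):
        p = rng.normal(size=(32, self.cfg.patch_dim))
        out = self.model.apply_mask(p, np.ones(32, dtype=bool))
        np.testing.assert_allclose(
            out.data, np.tile(self.model.mask_patch.data, (32, 1))
        )

    def test_single_index_locality(self, rng):
        p = rng.normal(size=(32, self.cfg.patch_dim))
        out = self.model.apply_mask(p, np.array([5]))
        differs = np.any(out.data != p, axis=1)
        assert differs[5] and differs.sum() == 1

    def test_out_of_range_index_rejected(self, rng):
        p = rng.normal(size=(32, self.cfg.patch_dim))
        with pytest.raises(ValidationError):
            self.model.apply_mask(p, np.array([40]))


class TestEncode:
    def test_output_shape(self, rng):
        cfg = ModelConfig(patch_length=1, embed_dim=32, n_blocks=2, n_heads=4,
                          ff_dim=64)
        model = PatchMaskedTransformer(cfg, rng=0)
        out = model.encode(rng.normal(size=(2, 128, 48)))
        assert out.shape == (2, 128, 32)

    def test_deterministic_without_dropout(self, rng):
        model = PatchMaskedTransformer(ModelConfig.tiny(), rng=0)
        x = rng.normal(size=(1, 32, 192))
        a = model.encode(x, training=False).data
        b = model.encode(x, training=False).data
        np.testing.assert_array_equal(a, b)

    def test_matches_dense_attention_oracle(self, rng):
        """Single-block, single-head, width-4 encoder against a from-scratch
        softmax(QKᵀ/√d)V + residual/LayerNorm/FF recomputation."""
        cfg = ModelConfig(patch_length=8, embed_dim=4, n_blocks=1, n_heads=1,
                          ff_dim=8, dropout=0.0, n_axes=2, window_length=128)
        model = PatchMaskedTransformer(cfg, rng=3)
        x = rng.normal(size=(1, 16, 16))
        out = model.encode(x).data[0]

        p = {k: v.data for k, v in model.parameters().items()}
        h = x[0] @ p["embed.w"] + p["embed.b"]
        h = h + model.positional

        def layer_norm(v, w, b, eps=1e-5):
            mu, var = v.mean(-1, keepdims=True), v.var(-1, keepdims=True)
            return (v - mu) / np.sqrt(var + eps) * w + b

        q = h @ p["block0.attn.q.w"] + p["block0.attn.q.b"]
        k = h @ p["block0.attn.k.w"] + p["block0.attn.k.b"]
        v = h @ p["block0.attn.v.w"] + p["block0.attn.v.b"]
        scores = q @ k.T / np.sqrt(4)
        attn = np.exp(scores - scores.max(-1, keepdims=True))
        attn = attn / attn.sum(-1, keepdims=True)
        ctx = (attn @ v) @ p["block0.attn.o.w"] + p["block0.attn.o.b"]
        h = layer_norm(h + ctx, p["block0.ln1_w"], p["block0.ln1_b"])
        ff = np.maximum(h @ p["block0.ff1.w"] + p["block0.ff1.b"], 0.0)
        ff = ff @ p["block0.ff2.w"] + p["block0.ff2.b"]
        expected = layer_norm(h + ff, p["block0.ln2_w"], p["block0.ln2_b"])
        assert np.abs(out - expected).max() < 1e-5


class TestHeads:
    def test_reconstruction_shape_and_linearity(self, rng):
        model = PatchMaskedTransformer(ModelConfig.tiny(), rng=0)
        emb = model.encode(rng.normal(size=(3, 32, 192)))
        rec = model.reconstruct(emb)
        assert rec.shape == (3, 128, 48)
        model._children["recon_head"].w.data[:] = 0
        model._children["recon_head"].b.data[:] = 0
        assert np.abs(model.reconstruct(emb).data).max() == 0

    def test_reconstruction_sensitive_to_mask_choice(self, rng):
        model = PatchMaskedTransformer(ModelConfig.tiny(), rng=0)
        w = rng.normal(size=(1, 128, 48))
        patches = slice_patches(w, 4)
        a = model.reconstruct(model.encode(model.apply_mask(patches, np.array([0])))).data
        b = model.reconstruct(model.encode(model.apply_mask(patches, np.array([9])))).data
        assert np.abs(a - b).max() > 0

    @pytest.mark.parametrize("patch_length,head_dim", [(1, 3), (4, 12), (8, 24)])
    def test_grf_head_dimension(self, rng, patch_length, head_dim):
        cfg = ModelConfig.tiny(patch_length=patch_length)
        model = PatchMaskedTransformer(cfg, rng=0, with_grf_head=True)
        assert model._children["grf_head"].w.shape == (64, head_dim)
        emb = model.encode(rng.normal(size=(2, cfg.n_patches, cfg.patch_dim)))
        assert model.predict_grf(emb).shape == (2, 128, 3)

    def test_zero_grf_head_gives_zero_output(self, rng):
        model = PatchMaskedTransformer(ModelConfig.tiny(), rng=0, with_grf_head=True)
        model._children["grf_head"].w.data[:] = 0
        model._children["grf_head"].b.data[:] = 0
        emb = model.encode(rng.normal(size=(1, 32, 192)))
        assert np.abs(model.predict_grf(emb).data).max() == 0


class TestSubstitution:
    def test_all_present_is_identity(self, rng):
        model = PatchMaskedTransformer(ModelConfig.tiny(), rng=0)
        w = rng.normal(size=(2, 128, 48))
        out = model.substitute_missing(w, CANONICAL_SENSORS)
        np.testing.assert_array_equal(out.data, w)

    @pytest.mark.parametrize("present,n_substituted", [
        (("r_foot",), 42),
        (("trunk", "r_thigh", "r_shank", "r_foot"), 24),
    ])
    def test_substituted_column_count(self, rng, present, n_substituted):
        omitted = tuple(s for s in CANONICAL_SENSORS if s not in present)
        model = PatchMaskedTransformer(ModelConfig.tiny(), rng=0,
                                       substituted_sensors=omitted)
        w = rng.normal(size=(2, 128, 48))
        out = model.substitute_missing(w, present).data
        changed = np.any(out != w, axis=(0, 1))
        assert changed.sum() == n_substituted
        for s in present:
            i = CANONICAL_SENSORS.index(s)
            np.testing.assert_array_equal(out[:, :, i * 6 : i * 6 + 6],
                                          w[:, :, i * 6 : i * 6 + 6])

    def test_substitution_tiles_over_time_patches(self, rng):
        cfg = ModelConfig.tiny()
        model = PatchMaskedTransformer(cfg, rng=0, substituted_sensors=("trunk",))
        out = model.substitute_missing(rng.normal(size=(1, 128, 48)),
                                       tuple(CANONICAL_SENSORS[1:])).data
        block = out[0, :4, 0:6]
        np.testing.assert_array_equal(out[0, :, 0:6],
                                      np.tile(block, (32, 1)))

    def test_no_present_sensors_rejected(self, rng):
        model = PatchMaskedTransformer(ModelConfig.tiny(), rng=0)
        with pytest.raises(ValidationError):
            model.substitute_missing(rng.normal(size=(1, 128, 48)), ())


class TestParameterCount:
    def test_toy_closed_form(self):
        cfg = ModelConfig(patch_length=1, embed_dim=4, n_blocks=1, n_heads=1,
                          ff_dim=8, n_axes=2, window_length=128)
        d, p, ff = 4, 2, 8
        embed = p * d + d
        attn = 4 * (d * d + d)
        lns = 2 * (2 * d)
        ffn = d * ff + ff + ff * d + d
        head = d * p + p
        mask = p
        assert count_parameters(cfg) == embed + attn + lns + ffn + head + mask

    def test_ff_increment_delta(self):
        base = ModelConfig(patch_length=1, embed_dim=64, n_blocks=3, n_heads=4,
                           ff_dim=128)
        bigger = ModelConfig(patch_length=1, embed_dim=64, n_blocks=3, n_heads=4,
                             ff_dim=160)
        delta = count_parameters(bigger) - count_parameters(base)
        assert delta == 3 * (2 * 64 * 32 + 32)

    def test_substitution_patches_counted_when_configured(self):
        cfg = ModelConfig.tiny()
        base = count_parameters(cfg)
        with_subs = count_parameters(cfg, substituted_sensors=("trunk", "pelvis"))
        assert with_subs == base + 2 * cfg.patch_length * 6


class TestCheckpoint:
    def test_bit_exact_roundtrip(self, tmp_path, rng):
        model = PatchMaskedTransformer(ModelConfig.tiny(), rng=5,
                                       substituted_sensors=("l_foot",))
        path = tmp_path / "ckpt.npz"
        model.save(path)
        back, stats = PatchMaskedTransformer.load(path)
        assert stats is None
        for k, p in model.parameters().items():
            assert np.abs(back.parameters()[k].data - p.data).max() == 0

    def test_config_mismatch_rejected(self, tmp_path):
        model = PatchMaskedTransformer(ModelConfig.tiny(), rng=0)
        path = tmp_path / "ckpt.npz"
        model.save(path)
        with pytest.raises(ConfigError):
            PatchMaskedTransformer.load(
                path, expected_config=ModelConfig.tiny(n_blocks=3)
            )


class TestMaskedLoss:
    def test_equals_brute_force_masked_mse(self, rng):
        """Loss equals an element-loop MSE over exactly the masked entries
        (|mask| x patch_length x 48 of them)."""
        cfg = ModelConfig.tiny()
        model = PatchMaskedTransformer(cfg, rng=0)
        X = rng.normal(size=(3, 128, 48))
        mask = np.zeros((3, cfg.n_patches), dtype=bool)
        for b in range(3):
            mask[b, rng.choice(cfg.n_patches, 4, replace=False)] = True
        loss = float(model.masked_reconstruction_loss(X, mask).data)

        patches = slice_patches(X, cfg.patch_length)
        masked = model.apply_mask(patches, mask)
        recon = model.reconstruct(model.encode(masked)).data
        total, count = 0.0, 0
        for b in range(3):
            for t in range(cfg.n_patches):
                if mask[b, t]:
                    rows = slice(t * cfg.patch_length, (t + 1) * cfg.patch_length)
                    total += ((recon[b, rows] - X[b, rows]) ** 2).sum()
                    count += cfg.patch_length * 48
        assert count == mask.sum() * cfg.patch_length * 48
        assert loss == pytest.approx(total / count, rel=1e-10)

    def test_mask_permutation_invariance(self, rng):
        cfg = ModelConfig.tiny()
        model = PatchMaskedTransformer(cfg, rng=0)
        X = rng.normal(size=(1, 128, 48))
        idx = np.array([2, 9, 17])
        a = model.apply_mask(slice_patches(X, 4), idx).data
        b = model.apply_mask(slice_patches(X, 4), idx[::-1].copy()).data
        np.testing.assert_array_equal(a, b)
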