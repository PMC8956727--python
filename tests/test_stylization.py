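"""Gram matrices, the style/content loss, generators and one-shot training."""

import numpy as np
import pytest

from petrisynth.datamodel import ColonyAnnotation, BoundingBox, SynthPatchRecord, ValidationError
from petrisynth.stylization import (
    FeatureExtractor,
    StyleConfig,
    assemble_tile,
    build_generator,
    gram,
    split_tile,
    style_content_loss,
    stylize_batch,
    train_stylizer,
)

SMALL_EXTRACTOR = FeatureExtractor(channels=(4, 6), seed=3)
SMALL_LAYERS = (0, 1)


def _cfg(**kw):
    defaults = dict(lambda_weight=0.05, feature_layers=SMALL_LAYERS, iterations=0,
                    tile_size=64, generator_arch="light")
    defaults.update(kw)
    return StyleConfig(**defaults)


class TestGram:
    def test_zero_features(self):
        assert not gram(np.zeros((3, 4, 4))).any()

    def test_constant_features_closed_form(self):
        # every channel constant v: G_ij = v^2 * HW / (C H W) = v^2 / C
        v, c = 3.0, 5
        g = gram(np.full((c, 4, 6), v))
        assert np.allclose(g, v * v / c)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        f = rng.normal(size=(3, 4, 4))
        flat = f.reshape(3, 16)
        expected = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                expected[i, j] = sum(flat[i, k] * flat[j, k] for k in range(16))
        expected /= 3 * 4 * 4
        assert np.allclose(gram(f), expected)

    def test_symmetric_psd(self):
        rng = np.random.default_rng(1)
        g = gram(rng.normal(size=(6, 5, 5)))
        assert np.allclose(g, g.T)
        assert np.linalg.eigvalsh(g).min() >= -1e-12


class TestStyleContentLoss:
    def setup_method(self):
        rng = np.random.default_rng(2)
        self.y = rng.uniform(0.2, 0.8, (16, 16, 3))
        self.yc = rng.uniform(0, 1, (16, 16, 3))
        self.ys = rng.uniform(0, 1, (12, 12, 3))  # style may differ in size

    def test_zero_at_content_with_zero_lambda(self):
        cfg = _cfg(lambda_weight=0.0)
        assert style_content_loss(self.y, self.y, self.ys, cfg, SMALL_EXTRACTOR) == 0.0

    def test_zero_at_style_with_unit_lambda(self):
        cfg = _cfg(lambda_weight=1.0)
        ys16 = np.random.default_rng(3).uniform(0, 1, (16, 16, 3))
        assert style_content_loss(ys16, self.yc, ys16, cfg, SMALL_EXTRACTOR) == 0.0

    def test_half_lambda_is_mean_of_terms(self):
        content_term = style_content_loss(self.y, self.yc, None,
                                          _cfg(lambda_weight=0.0), SMALL_EXTRACTOR)
        style_term = style_content_loss(self.y, None, self.ys,
                                        _cfg(lambda_weight=1.0), SMALL_EXTRACTOR)
        both = style_content_loss(self.y, self.yc, self.ys,
                                  _cfg(lambda_weight=0.5), SMALL_EXTRACTOR)
        assert both == pytest.approx((content_term + style_term) / 2.0, rel=1e-12)

    def test_nonnegative(self):
        cfg = _cfg(lambda_weight=0.3)
        assert style_content_loss(self.y, self.yc, self.ys, cfg, SMALL_EXTRACTOR) >= 0.0

    def test_gradient_matches_finite_differences(self):
        cfg = _cfg(lambda_weight=0.4)
        rng = np.random.default_rng(4)
        y = rng.uniform(0.2, 0.8, (8, 8, 3))
        yc = rng.uniform(0, 1, (8, 8, 3))
        ys = rng.uniform(0, 1, (8, 8, 3))
        _, g = style_content_loss(y, yc, ys, cfg, SMALL_EXTRACTOR, return_grad=True)
        eps = 1e-6
        for idx in [(0, 0, 0), (3, 4, 1), (7, 7, 2), (2, 5, 0)]:
            yp, ym = y.copy(), y.copy()
            yp[idx] += eps
            ym[idx] -= eps
            fd = (
                style_content_loss(yp, yc, ys, cfg, SMALL_EXTRACTOR)
                - style_content_loss(ym, yc, ys, cfg, SMALL_EXTRACTOR)
            ) / (2 * eps)
            assert abs(fd - g[idx]) / max(abs(fd), 1e-12) < 1e-3

    def test_empty_layer_list_rejected(self):
        with pytest.raises(ValidationError):
            StyleConfig(lambda_weight=0.05, feature_layers=(), tile_size=1024)


class TestGenerators:
    @pytest.mark.parametrize("arch", ["light", "highres"])
    @pytest.mark.parametrize("size", [16, 64])
    def test_shape_preserved(self, arch, size):
        gen = build_generator(arch, size)
        x = np.random.default_rng(0).uniform(0, 1, (size, size, 3))
        assert gen(x).shape == x.shape

    def test_light_smaller_than_highres(self):
        assert (build_generator("light", 64).n_parameters()
                < build_generator("highres", 64).n_parameters())

    def test_zero_head_is_identity(self):
        x = np.random.default_rng(1).uniform(0, 1, (16, 16, 3))
        for arch in ("light", "highres"):
            assert np.allclose(build_generator(arch, 16)(x), x)

    @pytest.mark.parametrize("arch", ["light", "highres"])
    def test_weight_gradients_match_finite_differences(self, arch):
        cfg = _cfg(lambda_weight=0.3)
        rng = np.random.default_rng(5)
        x = rng.uniform(0.2, 0.8, (8, 8, 3))
        ys = rng.uniform(0, 1, (8, 8, 3))
        gen = build_generator(arch, 8, np.random.default_rng(6), head_init="small")

        def loss():
            return style_content_loss(gen(x), x, ys, cfg, SMALL_EXTRACTOR)

        _, gy = style_content_loss(gen(x), x, ys, cfg, SMALL_EXTRACTOR, return_grad=True)
        gen.zero_grad()
        gen.backward_image(gy)
        eps, rr = 1e-6, np.random.default_rng(7)
        for name, conv in gen.convs.items():
            i = tuple(rr.integers(s) for s in conv.w.shape)
            old = conv.w[i]
            conv.w[i] = old + eps
            lp = loss()
            conv.w[i] = old - eps
            lm = loss()
            conv.w[i] = old
            fd = (lp - lm) / (2 * eps)
            if abs(fd) > 1e-10:
                assert abs(fd - conv.gw[i]) / abs(fd) < 1e-3, name

    def test_indivisible_size_rejected(self):
        with pytest.raises(ValidationError):
            build_generator("light", 30)


class TestTraining:
    def test_thirty_iterations_reduce_loss(self):
        rng = np.random.default_rng(0)
        content = rng.uniform(0.3, 0.7, (64, 64, 3))
        style = rng.uniform(0, 1, (48, 48, 3))
        cfg = _cfg(iterations=30, learning_rate=1e-2)
        _, losses = train_stylizer(content, style, cfg, seed=1)
        assert len(losses) == 30
        assert losses[-1] < losses[0]

    def test_zero_iterations_returns_initialization(self):
        rng = np.random.default_rng(1)
        content = rng.uniform(0, 1, (16, 16, 3))
        style = rng.uniform(0, 1, (16, 16, 3))
        cfg = _cfg(iterations=0, tile_size=16)
        weights, losses = train_stylizer(content, style, cfg, seed=2)
        ref = build_generator("light", 16, np.random.default_rng(2)).state_dict()
        assert losses == []
        for k in ref:
            assert (weights[k] == ref[k]).all()

    def test_warm_start_beats_cold_start(self):
        rng = np.random.default_rng(2)
        content = rng.uniform(0.3, 0.7, (32, 32, 3))
        style = rng.uniform(0, 1, (32, 32, 3))
        cfg = _cfg(iterations=20, tile_size=32, learning_rate=1e-2)
        wins = 0
        trials = 5
        for seed in range(trials):
            _, cold = train_stylizer(content, style, cfg, seed=seed)
            trained, _ = train_stylizer(content, style, cfg, seed=seed)
            _, warm = train_stylizer(content, style, cfg, init_weights=trained,
                                     seed=seed + 50)
            wins += warm[0] <= cold[0]
        assert wins / trials >= 0.8


class TestTileBatch:
    @staticmethod
    def _records(n, size, rng):
        recs = []
        for _ in range(n):
            img = rng.integers(0, 256, (size, size, 3), dtype=np.uint8)
            mask = np.zeros((size, size), dtype=bool)
            mask[4:9, 5:11] = True
            ann = ColonyAnnotation(BoundingBox(5, 4, 6, 5), "E.coli", 0)
            recs.append(SynthPatchRecord(img, [ann], [mask], {"style": "raw"}))
        return recs

    def test_assemble_split_round_trip(self):
        rng = np.random.default_rng(0)
        patches = [rng.integers(0, 256, (32, 32, 3), dtype=np.uint8) for _ in range(4)]
        tile = assemble_tile(patches)
        assert tile.shape == (64, 64, 3)
        back = split_tile(tile, 4)
        for a, b in zip(patches, back):
            assert (a == b).all()

    def test_identity_stylizer_keeps_patches(self):
        rng = np.random.default_rng(1)
        recs = self._records(4, 32, rng)
        cfg = _cfg(iterations=0, tile_size=64)
        styled, _ = stylize_batch(recs, rng.uniform(0, 1, (32, 32, 3)), cfg)
        for a, b in zip(recs, styled):
            assert (a.image == b.image).all()

    def test_annotations_copied_bit_exact(self):
        rng = np.random.default_rng(2)
        recs = self._records(4, 32, rng)
        cfg = _cfg(iterations=3, tile_size=64, learning_rate=1e-3)
        styled, _ = stylize_batch(recs, rng.uniform(0, 1, (24, 24, 3)), cfg)
        for a, b in zip(recs, styled):
            assert a.annotations == b.annotations
            for ma, mb in zip(a.masks, b.masks):
                assert (ma == mb).all()
            assert b.provenance["style"] != "raw"

    def test_patch_count_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        recs = self._records(3, 32, rng)
        with pytest.raises(ValidationError, match="patches"):
            stylize_batch(recs, rng.uniform(0, 1, (24, 24, 3)), _cfg(tile_size=64))


class TestLambdaEffect:
    def test_stronger_lambda_moves_output_toward_style(self):
        """Average style-term Gram distance decreases as lambda rises 0.02 -> 0.05."""
        xx, yy = np.meshgrid(np.linspace(0, 1, 64), np.linspace(0, 1, 64))
        content = np.dstack([0.5 + 0.3 * np.sin(8 * xx), 0.5 * np.ones_like(xx),
                             0.4 + 0.2 * yy])
        sx = np.meshgrid(np.linspace(0, 1, 48), np.linspace(0, 1, 48))[0]
        style = np.dstack([0.8 * np.ones((48, 48)), 0.2 + 0.6 * np.cos(6 * sx),
                           0.3 * np.ones((48, 48))])
        dist_cfg = _cfg(lambda_weight=1.0)

        def style_dist(y):
            return style_content_loss(y, None, style, dist_cfg, SMALL_EXTRACTOR)

        d02, d05 = [], []
        for seed in range(5):
            for lam, acc in ((0.02, d02), (0.05, d05)):
                cfg = _cfg(lambda_weight=lam, iterations=150, learning_rate=1e-2)
                w, _ = train_stylizer(content, style, cfg, extractor=SMALL_EXTRACTOR,
                                      seed=seed)
                gen = build_generator("light", 64)
                gen.load_state_dict(w)
                acc.append(style_dist(np.clip(gen(content), 0, 1)))
        assert np.mean(d05) <= np.mean(d02)


class TestConfigWarnings:
    def test_large_lambda_warns_not_errors(self):
        with pytest.warns(UserWarning, match="0.05"):
            StyleConfig(lambda_weight=0.2, tile_size=1024)
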