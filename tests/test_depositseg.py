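"""Pixel classification, covered area and the validation metrics."""

import numpy as np
import pytest

from lewyquant import depositseg
from lewyquant.depositseg import (
    DepositMask,
    FeatureConfig,
    PixelClassifierModel,
    area_accuracy,
    baseline_threshold_mask,
    classify_pixels,
    covered_area,
    extract_features,
    prediction_accuracy,
    preprocess_tile,
    train_classifier,
)
from lewyquant.synthcohort import DENSE_DEPOSIT, TileSpec, generate_tile


class TestFeatureConfig:
    def test_stack_depth_is_operators_times_scales_plus_raw(self):
        cfg = FeatureConfig(operators=("gaussian", "log"), scales=(1.0, 2.0, 4.0))
        assert cfg.n_features == 2 * 3 + 1
        feats = extract_features(np.zeros((16, 16)), cfg)
        assert feats.shape == (16, 16, cfg.n_features)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(operators=()),
            dict(scales=(2.0, 1.0)),
            dict(scales=(-1.0,)),
            dict(operators=("wavelet",)),
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FeatureConfig(**kwargs)


class TestExtractFeatures:
    def test_constant_image(self):
        cfg = FeatureConfig()
        feats = extract_features(np.full((24, 24), 0.5), cfg)
        # smoothing features stay at the constant; derivative features vanish
        for i, sigma in enumerate(cfg.scales):
            base = 1 + i * len(cfg.operators)
            smooth, log, grad, dog, var = (feats[..., base + k] for k in range(5))
            assert np.allclose(smooth, 0.5, atol=1e-6)
            for deriv in (log, grad, dog, var):
                assert np.allclose(deriv, 0.0, atol=1e-5)

    def test_impulse_log_response_extremal_at_impulse(self):
        img = np.zeros((33, 33))
        img[16, 16] = 1.0
        cfg = FeatureConfig(operators=("log",), scales=(1.6,))
        response = extract_features(img, cfg)[..., 1]
        assert np.unravel_index(np.abs(response).argmax(), response.shape) == (16, 16)

    def test_deterministic(self):
        img = np.random.default_rng(0).uniform(0, 1, (32, 32))
        assert np.array_equal(extract_features(img), extract_features(img))


class _ConstantForest:
    """Stub forest emitting a fixed deposit probability everywhere."""

    classes_ = np.array([False, True])

    def __init__(self, p):
        self.p = p

    def predict_proba(self, x):
        return np.column_stack([np.full(len(x), 1 - self.p), np.full(len(x), self.p)])


class TestClassifyPixels:
    def test_probability_just_below_threshold_gives_empty_mask(self):
        model = PixelClassifierModel(_ConstantForest(0.69), FeatureConfig(), "alpha_syn")
        mask = classify_pixels(np.zeros((8, 8)), model)
        assert not mask.mask.any()

    def test_probability_at_threshold_is_inclusive(self):
        model = PixelClassifierModel(_ConstantForest(0.70), FeatureConfig(), "alpha_syn")
        mask = classify_pixels(np.zeros((8, 8)), model)
        assert mask.mask.all()

    def test_threshold_monotonicity_never_increases_area(self, trained_segmentation):
        _, _, test_tiles, model, _ = trained_segmentation
        gray = preprocess_tile(test_tiles[0].image)
        prob = depositseg.predict_probability(gray, model)
        areas = [covered_area(prob >= thr) for thr in (0.3, 0.5, 0.7, 0.9)]
        assert all(a >= b for a, b in zip(areas, areas[1:]))

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            PixelClassifierModel(_ConstantForest(0.5), FeatureConfig(), "tau", threshold=1.0)


class TestCoveredArea:
    def test_empty_and_full(self):
        assert covered_area(np.zeros((10, 10), bool)) == 0.0
        assert covered_area(np.ones((10, 10), bool)) == 100.0

    def test_exact_arithmetic_full_tile(self):
        # 1,048,576 positives of a full 4096^2 tile denominator
        mask = np.ones((1024, 1024), bool)
        assert covered_area(mask, denominator=4096 * 4096) == 6.25

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            covered_area(np.ones((4, 4), bool), denominator=0)

    def test_union_equals_weighted_aggregate(self, rng):
        # disjoint tile masks: pooled covered area equals the
        # pixel-count-weighted mean of per-tile values
        masks = [rng.random((32, 64)) < p for p in (0.1, 0.4, 0.8)]
        union = np.concatenate(masks, axis=1)
        pooled = covered_area(union)
        weighted = sum(covered_area(m) * m.size for m in masks) / union.size
        assert pooled == pytest.approx(weighted)


class TestValidationMetrics:
    def test_prediction_accuracy_examples(self):
        a = np.zeros((10, 10), bool)
        assert prediction_accuracy(a, a) == 1.0
        assert prediction_accuracy(a, ~a) == 0.0
        b = a.copy().ravel()
        b[:10] = True
        assert prediction_accuracy(b.reshape(10, 10), a) == 0.9

    def test_prediction_accuracy_shape_mismatch(self):
        with pytest.raises(ValueError):
            prediction_accuracy(np.zeros((2, 2), bool), np.zeros((3, 3), bool))

    def test_area_accuracy_examples(self):
        assert area_accuracy(3.2, 3.2) == 1.0
        assert area_accuracy(2.0, 4.0) == 0.5
        assert area_accuracy(0.0, 0.0) == 1.0

    def test_area_accuracy_range_check(self):
        with pytest.raises(ValueError):
            area_accuracy(-1.0, 5.0)
        with pytest.raises(ValueError):
            area_accuracy(5.0, 120.0)


class TestTrainClassifier:
    def test_single_class_training_rejected(self):
        gray = np.zeros((16, 16))
        truth = np.zeros((16, 16), np.uint8)  # no deposit pixels at all
        with pytest.raises(ValueError):
            train_classifier([(gray, truth)], pixels_per_class=100)

    def test_same_seed_identical_predictions(self):
        tiles = [generate_tile(TileSpec(width=96, height=96, deposit_fraction_target=0.08, seed=s))
                 for s in (1, 2)]
        labeled = [(preprocess_tile(t.image), t.truth_mask) for t in tiles]
        kwargs = dict(n_trees=20, seed=5, pixels_per_class=2000)
        m1 = train_classifier(labeled, **kwargs)
        m2 = train_classifier(labeled, **kwargs)
        gray = labeled[0][0]
        assert np.array_equal(classify_pixels(gray, m1).mask, classify_pixels(gray, m2).mask)

    def test_heldout_accuracy_and_area_recovery(self, trained_segmentation):
        _, _, test_tiles, model, report = trained_segmentation
        assert report.mean_prediction_accuracy >= 0.9
        # synthetic tile at 5% dense deposit: covered area within 1.5 points
        tile = generate_tile(TileSpec(width=256, height=256, deposit_fraction_target=0.05, seed=77))
        pred = classify_pixels(preprocess_tile(tile.image), model)
        assert abs(covered_area(pred) - 100 * tile.deposit_fraction) <= 1.5

    def test_diffuse_stain_rarely_called_deposit(self, trained_segmentation):
        _, _, test_tiles, model, _ = trained_segmentation
        fpr = depositseg.diffuse_false_positive_rate(model, test_tiles)
        assert fpr < 0.05

    def test_classifier_beats_trivial_threshold_baseline(self, trained_segmentation):
        _, _, test_tiles, model, report = trained_segmentation
        best_baseline = 0.0
        for cutoff in np.arange(0.06, 0.42, 0.04):
            acc = np.mean([
                prediction_accuracy(
                    baseline_threshold_mask(preprocess_tile(t.image), cutoff),
                    t.truth_mask == DENSE_DEPOSIT,
                )
                for t in test_tiles
            ])
            best_baseline = max(best_baseline, float(acc))
        assert report.mean_prediction_accuracy > best_baseline


class TestModelSerialization:
    def test_save_load_roundtrip(self, trained_segmentation, tmp_path):
        _, _, test_tiles, model, _ = trained_segmentation
        path = tmp_path / "model.joblib"
        depositseg.save_model(model, path)
        loaded = depositseg.load_model(path)
        gray = preprocess_tile(test_tiles[0].image)
        assert np.array_equal(
            classify_pixels(gray, model).mask, classify_pixels(gray, loaded).mask
        )
        assert loaded.threshold == model.threshold
        assert loaded.feature_config == model.feature_config
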