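"""Pixel-level deposit segmentation and covered-area quantification.

Preprocessed DAB grayscale tiles are classified pixel-wise by a random
forest over a multiscale filter bank (ilastik-style: smoothed intensity,
Laplacian of Gaussian, gradient magnitude, difference of Gaussians and a
local-variance texture measure at sigma in {0.7, 1.6, 3.5, 7.0} px).  The
deposit class probability is thresholded at 0.7 (inclusive) to produce a
binary deposit mask; the fraction of positive pixels in an annotated region
is the *covered area* (or *load*), expressed in percent.

Two validation metrics compare a prediction with a reference segmentation:
``prediction_accuracy`` (fraction of pixels labeled identically) and
``area_accuracy`` (agreement of total covered area irrespective of pixel
localization, here 1 - |pred - ref| / max(pred, ref)).

The alpha-synuclein model is deliberately trained to call only *dense*
deposits positive: diffuse physiological synaptic staining is labeled
negative in the training masks, so the forest learns to ignore it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .synthcohort import DENSE_DEPOSIT, SyntheticTile
from . import stainsep

__all__ = [
    "FeatureConfig",
    "PixelClassifierModel",
    "DepositMask",
    "ValidationReport",
    "extract_features",
    "train_classifier",
    "classify_pixels",
    "covered_area",
    "prediction_accuracy",
    "area_accuracy",
    "validate_model",
    "preprocess_tile",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1

_OPERATORS = ("gaussian", "log", "gradient", "dog", "variance")


@dataclass(frozen=True)
class FeatureConfig:
    """Per-pixel feature bank: operators x scales, plus the raw intensity."""

    operators: tuple[str, ...] = _OPERATORS
    scales: tuple[float, ...] = (0.7, 1.6, 3.5, 7.0)
    include_raw: bool = True

    def __post_init__(self) -> None:
        if not self.operators:
            raise ValueError("at least one operator is required")
        unknown = set(self.operators) - set(_OPERATORS)
        if unknown:
            raise ValueError(f"unknown operators: {sorted(unknown)}")
        scales = tuple(float(s) for s in self.scales)
        if not scales or any(s <= 0 for s in scales):
            raise ValueError("scales must be positive")
        if any(b <= a for a, b in zip(scales, scales[1:])):
            raise ValueError("scales must be strictly increasing")
        object.__setattr__(self, "scales", scales)

    @property
    def n_features(self) -> int:
        return len(self.operators) * len(self.scales) + (1 if self.include_raw else 0)


def extract_features(gray: np.ndarray, cfg: FeatureConfig | None = None) -> np.ndarray:
    """Compute the feature stack for a [0, 1] grayscale tile.

    Returns an H x W x F array, F = |operators| x |scales| (+1 raw).
    Deterministic: pure filtering, no randomness.
    """
    cfg = cfg or FeatureConfig()
    gray = np.asarray(gray, dtype=np.float32)
    if gray.ndim != 2:
        raise ValueError("expected a single-channel tile")
    planes: list[np.ndarray] = []
    if cfg.include_raw:
        planes.append(gray)
    for sigma in cfg.scales:
        smoothed = ndimage.gaussian_filter(gray, sigma)
        for op in cfg.operators:
            if op == "gaussian":
                planes.append(smoothed)
            elif op == "log":
                # the truncated discrete LoG kernel leaks a small DC term at
                # small sigma; subtract it so constants map to exactly zero
                m = int(8 * sigma) + 3
                k0 = ndimage.gaussian_laplace(np.ones((m, m), np.float32), sigma)[m // 2, m // 2]
                planes.append(ndimage.gaussian_laplace(gray, sigma) - k0 * gray)
            elif op == "gradient":
                planes.append(ndimage.gaussian_gradient_magnitude(gray, sigma))
            elif op == "dog":
                planes.append(smoothed - ndimage.gaussian_filter(gray, 1.6 * sigma))
            elif op == "variance":
                mean_sq = ndimage.gaussian_filter(gray * gray, sigma)
                planes.append(np.maximum(mean_sq - smoothed * smoothed, 0.0))
    return np.stack(planes, axis=-1).astype(np.float32)


@dataclass
class PixelClassifierModel:
    """A trained per-stain pixel classifier with its preprocessing contract."""

    forest: RandomForestClassifier
    feature_config: FeatureConfig
    stain: str
    threshold: float = 0.7
    training_tiles: tuple[str, ...] = ()
    seed: int = 0
    format_version: int = MODEL_FORMAT_VERSION

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")


@dataclass(frozen=True)
class DepositMask:
    mask: np.ndarray  # H x W bool
    tile_id: str = ""
    model_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))


@dataclass(frozen=True)
class ValidationReport:
    tile_ids: tuple[str, ...]
    prediction_accuracies: tuple[float, ...]
    area_accuracies: tuple[float, ...]
    predicted_areas: tuple[float, ...]
    reference_areas: tuple[float, ...]

    @property
    def mean_prediction_accuracy(self) -> float:
        return float(np.mean(self.prediction_accuracies))

    @property
    def mean_area_accuracy(self) -> float:
        return float(np.mean(self.area_accuracies))


def preprocess_tile(tile_rgb: np.ndarray, vectors: stainsep.StainVectorSet | None = None) -> np.ndarray:
    """RGB tile -> normalized DAB grayscale (deconvolution + fixed rescale)."""
    od = stainsep.deconvolve(tile_rgb, vectors, stain="dab")
    return stainsep.to_grayscale(od)


def _subsample(idx: np.ndarray, budget: int, rng: np.random.Generator) -> np.ndarray:
    if idx.size <= budget:
        return idx
    return rng.choice(idx, size=budget, replace=False)


def train_classifier(
    labeled_tiles: list[tuple[np.ndarray, np.ndarray]],
    cfg: FeatureConfig | None = None,
    n_trees: int = 100,
    seed: int = 0,
    stain: str = "alpha_syn",
    threshold: float = 0.7,
    pixels_per_class: int = 200_000,
    tile_ids: tuple[str, ...] = (),
) -> PixelClassifierModel:
    """Train a deposit-vs-rest random forest on labeled grayscale tiles.

    ``labeled_tiles`` pairs a [0, 1] grayscale tile with a truth mask whose
    dense-deposit code marks positives; every other label (background,
    nucleus, diffuse physiological staining) is negative.  Pixels are
    subsampled to ``pixels_per_class`` per class (deposits are rare, so
    balanced subsampling keeps the forest from ignoring them).
    """
    cfg = cfg or FeatureConfig()
    if not labeled_tiles:
        raise ValueError("no training tiles")
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for gray, truth in labeled_tiles:
        feats = extract_features(gray, cfg).reshape(-1, cfg.n_features)
        labels = (np.asarray(truth).ravel() == DENSE_DEPOSIT)
        xs.append(feats)
        ys.append(labels)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    pos = np.flatnonzero(y)
    neg = np.flatnonzero(~y)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("training data must contain both deposit and non-deposit pixels")
    keep = np.concatenate([
        _subsample(pos, pixels_per_class, rng),
        _subsample(neg, pixels_per_class, rng),
    ])
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=int(rng.integers(2**31 - 1)), n_jobs=1
    )
    forest.fit(x[keep], y[keep])
    return PixelClassifierModel(
        forest=forest, feature_config=cfg, stain=stain, threshold=threshold,
        training_tiles=tuple(tile_ids), seed=seed,
    )


def predict_probability(gray: np.ndarray, model: PixelClassifierModel) -> np.ndarray:
    """Per-pixel deposit-class probability map."""
    feats = extract_features(gray, model.feature_config)
    flat = feats.reshape(-1, model.feature_config.n_features)
    proba = model.forest.predict_proba(flat)
    pos_col = int(np.flatnonzero(model.forest.classes_ == True)[0])  # noqa: E712
    return proba[:, pos_col].reshape(gray.shape)


def classify_pixels(gray: np.ndarray, model: PixelClassifierModel, tile_id: str = "") -> DepositMask:
    """Binary segmentation: deposit probability >= threshold (inclusive)."""
    prob = predict_probability(gray, model)
    return DepositMask(mask=prob >= model.threshold, tile_id=tile_id, model_id=model.stain)


def covered_area(mask: DepositMask | np.ndarray, denominator: int | None = None) -> float:
    """Percent of annotation pixels classified deposit-positive.

    ``denominator`` defaults to the mask size; for partial edge tiles pass
    the true in-annotation pixel count.
    """
    arr = mask.mask if isinstance(mask, DepositMask) else np.asarray(mask, dtype=bool)
    denom = arr.size if denominator is None else int(denominator)
    if denom <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * float(arr.sum()) / denom


def prediction_accuracy(pred: DepositMask | np.ndarray, ref: DepositMask | np.ndarray) -> float:
    """Fraction of pixels with identical labels."""
    a = pred.mask if isinstance(pred, DepositMask) else np.asarray(pred, dtype=bool)
    b = ref.mask if isinstance(ref, DepositMask) else np.asarray(ref, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("shape mismatch between prediction and reference")
    return float((a == b).mean())


def area_accuracy(pred_area: float, ref_area: float) -> float:
    """Covered-area agreement irrespective of localization.

    1 - |pred - ref| / max(pred, ref); defined as 1 when both areas are 0.
    """
    for v in (pred_area, ref_area):
        if not (0.0 <= v <= 100.0):
            raise ValueError("areas must lie in [0, 100] percent")
    m = max(pred_area, ref_area)
    if m == 0:
        return 1.0
    return 1.0 - abs(pred_area - ref_area) / m


def validate_model(
    model: PixelClassifierModel,
    test_tiles: list[SyntheticTile],
) -> ValidationReport:
    """Evaluate a model against ground-truth masks of independent tiles."""
    tile_ids, pred_acc, area_acc, pred_areas, ref_areas = [], [], [], [], []
    for i, tile in enumerate(test_tiles):
        gray = preprocess_tile(tile.image)
        pred = classify_pixels(gray, model, tile_id=str(i))
        ref = tile.truth_mask == DENSE_DEPOSIT
        pa = covered_area(pred)
        ra = covered_area(ref)
        tile_ids.append(str(i))
        pred_acc.append(prediction_accuracy(pred, ref))
        area_acc.append(area_accuracy(pa, ra))
        pred_areas.append(pa)
        ref_areas.append(ra)
    return ValidationReport(
        tile_ids=tuple(tile_ids),
        prediction_accuracies=tuple(pred_acc),
        area_accuracies=tuple(area_acc),
        predicted_areas=tuple(pred_areas),
        reference_areas=tuple(ref_areas),
    )


def diffuse_false_positive_rate(model: PixelClassifierModel, tiles: list[SyntheticTile]) -> float:
    """Fraction of diffuse-physiological-stain pixels called deposit.

    The alpha-syn model contract is to detect dense deposits while ignoring
    diffuse synaptic staining; this measures that directly.
    """
    from .synthcohort import DIFFUSE_STAIN

    fp = 0
    total = 0
    for tile in tiles:
        gray = preprocess_tile(tile.image)
        pred = classify_pixels(gray, model).mask
        diffuse = tile.truth_mask == DIFFUSE_STAIN
        fp += int((pred & diffuse).sum())
        total += int(diffuse.sum())
    if total == 0:
        raise ValueError("no diffuse-stain pixels in the supplied tiles")
    return fp / total


def baseline_threshold_mask(gray: np.ndarray, cutoff: float = 0.25) -> np.ndarray:
    """Trivial OD-threshold baseline segmentation (comparison yardstick)."""
    return np.asarray(gray) >= cutoff


def save_model(model: PixelClassifierModel, path) -> None:
    joblib.dump(
        {
            "format_version": model.format_version,
            "forest": model.forest,
            "feature_config": model.feature_config,
            "stain": model.stain,
            "threshold": model.threshold,
            "training_tiles": model.training_tiles,
            "seed": model.seed,
        },
        path,
    )


def load_model(path) -> PixelClassifierModel:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {payload.get('format_version')}")
    return PixelClassifierModel(
        forest=payload["forest"],
        feature_config=payload["feature_config"],
        stain=payload["stain"],
        threshold=payload["threshold"],
        training_tiles=tuple(payload["training_tiles"]),
        seed=payload["seed"],
    )
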