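"""Trainable two-class random-forest pixel classifier (fat lumen vs stained tissue).

The classifier operates per pixel on a multiscale filter bank — Gaussian
smoothing, gradient magnitude and Laplacian of Gaussian per RGB channel — at a
fixed working resolution, and assigns each working pixel to one of two
classes: unstained *fat* lumen or stained *tissue* (membranes plus anything
else that takes up stain). Distinguishing membranes from other stained
structures is deliberately not attempted: lumen-vs-any-tissue is the robust
formulation for adipose H&E material.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import Polygon
from sklearn.ensemble import RandomForestClassifier
from skimage.draw import polygon as draw_polygon

from .image import CalibratedImage, ClassMask, resample_to_working

__all__ = [
    "FeatureSpec",
    "default_feature_config",
    "extract_features",
    "PixelClassifierModel",
    "TrainingError",
    "train_classifier",
    "retrain_classifier",
    "classify_pixels",
    "save_model",
    "load_model",
]

LABEL_UNLABELLED, LABEL_FAT, LABEL_TISSUE = 0, 1, 2
CLASS_NAMES = {LABEL_FAT: "fat", LABEL_TISSUE: "tissue"}

FILTERS = ("gaussian", "gradmag", "log")

# One feature = (channel index, filter name, sigma in working pixels).
FeatureSpec = tuple[int, str, float]


class TrainingError(ValueError):
    """Raised when training annotations cannot support a two-class model."""


def default_feature_config(sigmas: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)) -> list[FeatureSpec]:
    """Raw R, G, B plus smoothed intensity, gradient magnitude and LoG per
    channel at each scale (39 features for the default four scales)."""
    config: list[FeatureSpec] = [(c, "gaussian", 0.0) for c in range(3)]
    for sigma in sigmas:
        for c in range(3):
            for filt in FILTERS:
                config.append((c, filt, float(sigma)))
    return config


def extract_features(
    image: CalibratedImage,
    feature_config: list[FeatureSpec] | None = None,
    working_pixel_size_um: float = 1.0,
) -> np.ndarray:
    """Per-pixel feature stack ``(H', W', F)`` at the working resolution.

    The image is resampled to ``working_pixel_size_um`` first, then filtered;
    sigma 0 with the ``gaussian`` filter is the identity (the resampled
    channel itself).
    """
    if feature_config is None:
        feature_config = default_feature_config()
    if not feature_config:
        raise ValueError("feature_config must be non-empty")
    pixels = resample_to_working(image, working_pixel_size_um)
    h, w = pixels.shape[:2]
    max_sigma = max(s for _, _, s in feature_config)
    if max_sigma > min(h, w):
        raise ValueError(
            f"feature scale sigma={max_sigma}px exceeds image extent {min(h, w)}px"
        )
    channels = [pixels[:, :, c] for c in range(3)]
    out = np.empty((h, w, len(feature_config)), dtype=np.float32)
    cache: dict[tuple[int, str, float], np.ndarray] = {}
    for f, (c, filt, sigma) in enumerate(feature_config):
        key = (c, filt, sigma)
        if key not in cache:
            cache[key] = _apply_filter(channels[c], filt, sigma)
        out[:, :, f] = cache[key]
    return out


def _apply_filter(channel: np.ndarray, filt: str, sigma: float) -> np.ndarray:
    if sigma == 0:
        if filt != "gaussian":
            raise ValueError(f"sigma=0 only valid for the identity gaussian, not {filt}")
        return channel
    if filt == "gaussian":
        return ndi.gaussian_filter(channel, sigma)
    if filt == "gradmag":
        gy = ndi.gaussian_filter(channel, sigma, order=(1, 0))
        gx = ndi.gaussian_filter(channel, sigma, order=(0, 1))
        return np.hypot(gx, gy)
    if filt == "log":
        return ndi.gaussian_laplace(channel, sigma)
    raise ValueError(f"unknown filter {filt!r}; expected one of {FILTERS}")


@dataclass
class PixelClassifierModel:
    """A trained lumen/tissue forest plus everything needed to re-apply it.

    The pooled training matrix is retained so a user can append annotations
    for misclassified regions and retrain incrementally, mirroring the
    annotate–review–retrain loop of interactive pixel classification.
    """

    forest: RandomForestClassifier
    feature_config: list[FeatureSpec]
    working_pixel_size_um: float
    train_seed: int
    oob_accuracy: float
    training_X: np.ndarray
    training_y: np.ndarray
    class_labels: dict[int, str] = field(default_factory=lambda: dict(CLASS_NAMES))
    model_id: str = "adipoquant-pixel-classifier"

    def predict_fat_probability(self, features_flat: np.ndarray) -> np.ndarray:
        col = list(self.forest.classes_).index(LABEL_FAT)
        return self.forest.predict_proba(features_flat)[:, col]


def _labels_to_working(
    label_mask: np.ndarray,
    src_pixel_size: float,
    working_pixel_size: float,
    working_shape: tuple[int, int],
) -> np.ndarray:
    """Map an image-resolution scribble mask onto the working grid.

    Each labelled source pixel votes for the working pixel containing its
    centre; conflicting votes (rare, only when scribbles of both classes fall
    in one working pixel) are discarded.
    """
    out = np.zeros(working_shape, dtype=np.uint8)
    conflict = np.zeros(working_shape, dtype=bool)
    scale = src_pixel_size / working_pixel_size
    for cls in (LABEL_FAT, LABEL_TISSUE):
        rr, cc = np.nonzero(label_mask == cls)
        wr = np.clip(((rr + 0.5) * scale).astype(int), 0, working_shape[0] - 1)
        wc = np.clip(((cc + 0.5) * scale).astype(int), 0, working_shape[1] - 1)
        taken = out[wr, wc]
        conflict[wr[(taken != 0) & (taken != cls)], wc[(taken != 0) & (taken != cls)]] = True
        out[wr, wc] = cls
    out[conflict] = LABEL_UNLABELLED
    return out


def _collect_training_data(
    annotated_images: list[tuple[CalibratedImage, np.ndarray]],
    feature_config: list[FeatureSpec],
    working_pixel_size_um: float,
) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for image, label_mask in annotated_images:
        if label_mask.shape != image.shape:
            raise ValueError("label mask shape must match image shape")
        feats = extract_features(image, feature_config, working_pixel_size_um)
        wlab = _labels_to_working(
            label_mask, image.require_calibration(), working_pixel_size_um, feats.shape[:2]
        )
        sel = wlab != LABEL_UNLABELLED
        xs.append(feats[sel])
        ys.append(wlab[sel])
    X = np.concatenate(xs, axis=0)
    y = np.concatenate(ys, axis=0)
    return X, y


def _fit_forest(
    X: np.ndarray, y: np.ndarray, n_estimators: int, seed: int
) -> tuple[RandomForestClassifier, float]:
    present = set(np.unique(y).tolist())
    for cls in (LABEL_FAT, LABEL_TISSUE):
        if cls not in present:
            raise TrainingError(
                f"annotations contain no '{CLASS_NAMES[cls]}' pixels; both classes "
                "must be represented"
            )
    forest = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features="sqrt",
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return forest, float(forest.oob_score_)


def train_classifier(
    annotated_images: list[tuple[CalibratedImage, np.ndarray]],
    feature_config: list[FeatureSpec] | None = None,
    working_pixel_size_um: float = 1.0,
    n_estimators: int = 100,
    seed: int = 0,
) -> PixelClassifierModel:
    """Train the lumen/tissue forest from sparse scribble annotations.

    ``annotated_images`` pairs each calibrated image with an image-resolution
    label mask (0 unlabelled, 1 fat, 2 tissue). Both classes must be present
    in the pool. Deterministic for a fixed ``seed``; the model's
    ``oob_accuracy`` is the forest's out-of-bag pixel accuracy.
    """
    if feature_config is None:
        feature_config = default_feature_config()
    if not annotated_images:
        raise TrainingError("at least one annotated image is required")
    for image, _ in annotated_images:
        if working_pixel_size_um < image.require_calibration() - 1e-12:
            raise ValueError("working pixel size must be >= source pixel size")
    X, y = _collect_training_data(annotated_images, feature_config, working_pixel_size_um)
    forest, oob = _fit_forest(X, y, n_estimators, seed)
    return PixelClassifierModel(
        forest=forest,
        feature_config=feature_config,
        working_pixel_size_um=working_pixel_size_um,
        train_seed=seed,
        oob_accuracy=oob,
        training_X=X,
        training_y=y,
    )


def retrain_classifier(
    model: PixelClassifierModel,
    additional_annotated_images: list[tuple[CalibratedImage, np.ndarray]],
) -> PixelClassifierModel:
    """Refit with extra annotations appended to the stored training pool."""
    X_new, y_new = _collect_training_data(
        additional_annotated_images, model.feature_config, model.working_pixel_size_um
    )
    X = np.concatenate([model.training_X, X_new], axis=0)
    y = np.concatenate([model.training_y, y_new], axis=0)
    forest, oob = _fit_forest(X, y, model.forest.n_estimators, model.train_seed)
    return PixelClassifierModel(
        forest=forest,
        feature_config=model.feature_config,
        working_pixel_size_um=model.working_pixel_size_um,
        train_seed=model.train_seed,
        oob_accuracy=oob,
        training_X=X,
        training_y=y,
        class_labels=dict(model.class_labels),
        model_id=model.model_id,
    )


def classify_pixels(
    model: PixelClassifierModel,
    image: CalibratedImage,
    roi_polygon: Polygon | None = None,
    image_id: str = "",
) -> ClassMask:
    """Apply the trained model; returns the binary fat mask at working resolution.

    Fat is called where the forest's fat vote fraction is ≥ 0.5. Pixels
    outside ``roi_polygon`` (µm slide coordinates) are forced to tissue. A
    pure function of (model, image, ROI): repeated calls are identical.
    """
    image.require_calibration()
    feats = extract_features(image, model.feature_config, model.working_pixel_size_um)
    h, w = feats.shape[:2]
    proba = model.predict_fat_probability(feats.reshape(-1, feats.shape[2]))
    mask = (proba >= 0.5).reshape(h, w)
    if roi_polygon is not None:
        mask &= _rasterize_roi(roi_polygon, image, model.working_pixel_size_um, (h, w))
    return ClassMask(
        mask=mask,
        pixel_size_um=model.working_pixel_size_um,
        origin_um=image.origin_um,
        provenance=f"{model.model_id}|{image_id}",
    )


def _rasterize_roi(
    roi: Polygon,
    image: CalibratedImage,
    working_pixel_size: float,
    shape: tuple[int, int],
) -> np.ndarray:
    ox, oy = image.origin_um
    geoms = roi.geoms if roi.geom_type != "Polygon" else [roi]
    out = np.zeros(shape, dtype=bool)
    for g in geoms:
        x, y = g.exterior.coords.xy
        rows = (np.asarray(y) - oy) / working_pixel_size - 0.5
        cols = (np.asarray(x) - ox) / working_pixel_size - 0.5
        rr, cc = draw_polygon(rows, cols, shape=shape)
        out[rr, cc] = True
    return out


# ---------------------------------------------------------------------------
# Serialization: one versioned joblib container per model.

_MODEL_FORMAT_VERSION = 1


def save_model(model: PixelClassifierModel, path: str | Path) -> None:
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "model_id": model.model_id,
        "forest": model.forest,
        "feature_config": model.feature_config,
        "working_pixel_size_um": model.working_pixel_size_um,
        "train_seed": model.train_seed,
        "oob_accuracy": model.oob_accuracy,
        "training_X": model.training_X,
        "training_y": model.training_y,
        "class_labels": model.class_labels,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> PixelClassifierModel:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version: {version}")
    return PixelClassifierModel(
        forest=payload["forest"],
        feature_config=[tuple(f) for f in payload["feature_config"]],
        working_pixel_size_um=payload["working_pixel_size_um"],
        train_seed=payload["train_seed"],
        oob_accuracy=payload["oob_accuracy"],
        training_X=payload["training_X"],
        training_y=payload["training_y"],
        class_labels=payload["class_labels"],
        model_id=payload["model_id"],
    )
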