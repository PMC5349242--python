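"""Five-class signal classification from raw 13x13 RGB patch features.

Each detected circle is cut out as a 13x13 patch centred on the
detection, flattened channel-major to a 507-vector (169 pixels x 3
channels, scaled to [0, 1]) and classified by an RBF-kernel SVM into
PTEN, CEP10, MIXED, WHITE or BLUE.  The model is selected by 5-fold
stratified cross-validation over a full (C, gamma) grid; ties are
broken toward the smallest C, then the smallest gamma.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .detection import Detection
from .image_io import CoreImage
from .labels import CLASSES

PATCH_SIZE = 13
FEATURE_LENGTH = PATCH_SIZE * PATCH_SIZE * 3  # 507

#: default background fill for patches that overhang the image border
DEFAULT_FILL = (245, 242, 240)

#: conventional coarse log2 grids for the RBF-SVM search
DEFAULT_C_GRID = tuple(2.0 ** k for k in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0 ** k for k in range(-15, 4, 2))

MODEL_FORMAT_VERSION = 1

__all__ = [
    "PATCH_SIZE",
    "FEATURE_LENGTH",
    "PatchSample",
    "TrainedClassifier",
    "ClassifiedSignal",
    "extract_patch",
    "featurize",
    "featurize_patches",
    "train_classifier",
    "classify_detections",
    "save_model",
    "load_model",
    "write_signals",
    "read_signals",
]


@dataclass
class PatchSample:
    """A feature vector with an optional class label."""

    features: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=np.float64)
        if f.shape != (FEATURE_LENGTH,):
            raise ValueError(f"features must have length {FEATURE_LENGTH}")
        if f.min() < 0.0 or f.max() > 1.0:
            raise ValueError("features must lie in [0, 1]")
        if self.label is not None and self.label not in CLASSES:
            raise ValueError(f"unknown label {self.label!r}")
        self.features = f


@dataclass
class TrainedClassifier:
    """A fitted five-class SVM plus its selection metadata."""

    estimator: SVC
    C: float
    gamma: float
    cv_accuracy: float
    classes: tuple[str, ...]
    grid: list[tuple[float, float]] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(X)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Max one-vs-rest-aggregated decision value per sample."""
        dec = self.estimator.decision_function(X)
        if dec.ndim == 1:  # binary edge case
            return np.abs(dec)
        return dec.max(axis=1)


@dataclass(frozen=True)
class ClassifiedSignal:
    """A detection with its class label and decision confidence."""

    detection: Detection
    label: str
    score: float

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"unknown label {self.label!r}")


def extract_patch(image: np.ndarray | CoreImage, centre_xy,
                  size: int = PATCH_SIZE,
                  fill: tuple[int, int, int] = DEFAULT_FILL) -> np.ndarray:
    """Cut a ``size`` x ``size`` RGB window centred at the rounded centre.

    Out-of-bounds pixels are filled with the background fill value, so
    detections near the border still yield a full-size patch.
    """
    if size % 2 == 0:
        raise ValueError("patch size must be odd")
    pixels = image.pixels if isinstance(image, CoreImage) else np.asarray(image)
    h, w = pixels.shape[:2]
    cx, cy = int(round(centre_xy[0])), int(round(centre_xy[1]))
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError(f"centre {centre_xy} outside image {w}x{h}")
    half = size // 2
    patch = np.empty((size, size, 3), dtype=np.uint8)
    patch[:] = np.asarray(fill, np.uint8)
    x0, x1 = cx - half, cx + half + 1
    y0, y1 = cy - half, cy + half + 1
    sx0, sy0 = max(0, x0), max(0, y0)
    sx1, sy1 = min(w, x1), min(h, y1)
    patch[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = pixels[sy0:sy1, sx0:sx1]
    return patch


def featurize(patch: np.ndarray) -> np.ndarray:
    """Flatten a 13x13x3 patch channel-major (R-plane | G | B), scaled /255."""
    patch = np.asarray(patch)
    if patch.shape != (PATCH_SIZE, PATCH_SIZE, 3):
        raise ValueError(f"expected a {PATCH_SIZE}x{PATCH_SIZE}x3 patch, "
                         f"got {patch.shape}")
    planes = [patch[..., c].ravel() for c in range(3)]
    return np.concatenate(planes).astype(np.float64) / 255.0


def unfeaturize(features: np.ndarray) -> np.ndarray:
    """Inverse of :func:`featurize` up to uint8 quantization."""
    f = np.asarray(features, dtype=np.float64)
    if f.shape != (FEATURE_LENGTH,):
        raise ValueError(f"features must have length {FEATURE_LENGTH}")
    planes = (f * 255.0).round().reshape(3, PATCH_SIZE, PATCH_SIZE)
    return np.moveaxis(planes, 0, -1).astype(np.uint8)


def featurize_patches(patches: np.ndarray) -> np.ndarray:
    """Vectorised featurize over an ``(n, 13, 13, 3)`` patch stack."""
    patches = np.asarray(patches)
    n = patches.shape[0]
    planes = np.moveaxis(patches, -1, 1).reshape(n, FEATURE_LENGTH)
    return planes.astype(np.float64) / 255.0


def _fold_assignment(y: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Stratified fold labels per sample, deterministic in the seed."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for k, (_, val_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[val_idx] = k
    return assignment


def train_classifier(X: np.ndarray, y: np.ndarray, folds: int = 5,
                     c_grid=DEFAULT_C_GRID, gamma_grid=DEFAULT_GAMMA_GRID,
                     seed: int = 0,
                     fold_assignment: np.ndarray | None = None,
                     ) -> TrainedClassifier:
    """Grid-search an RBF SVM by k-fold cross-validation and refit.

    Every (C, gamma) pair of the grid is scored by mean CV accuracy on
    stratified folds drawn from ``seed`` (or an explicit per-sample
    ``fold_assignment``); the best pair -- smallest C then smallest
    gamma on ties -- is refitted on all samples.

    Requires all five classes present with at least ``folds`` samples
    each.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] != FEATURE_LENGTH:
        raise ValueError(f"X must be (n, {FEATURE_LENGTH})")
    present = set(np.unique(y))
    missing = [c for c in CLASSES if c not in present]
    if missing:
        raise ValueError("missing class(es) in training data: " + ", ".join(missing))
    counts = pd.Series(y).value_counts()
    thin = counts[counts < folds]
    if len(thin):
        raise ValueError(
            "class(es) with fewer samples than folds: "
            + ", ".join(f"{c} ({n})" for c, n in thin.items())
        )

    if fold_assignment is None:
        fold_assignment = _fold_assignment(y, folds, seed)
    else:
        fold_assignment = np.asarray(fold_assignment, dtype=int)
        if fold_assignment.shape != (len(y),):
            raise ValueError("fold_assignment must give one fold per sample")

    fold_ids = np.unique(fold_assignment)
    splits = [(fold_assignment != k, fold_assignment == k) for k in fold_ids]

    best: tuple[float, float, float] | None = None  # (acc, C, gamma)
    grid = [(float(C), float(g)) for C in sorted(c_grid) for g in sorted(gamma_grid)]
    for C, gamma in grid:
        correct = 0
        for train_mask, val_mask in splits:
            clf = SVC(kernel="rbf", C=C, gamma=gamma, cache_size=200)
            clf.fit(X[train_mask], y[train_mask])
            correct += int((clf.predict(X[val_mask]) == y[val_mask]).sum())
        acc = correct / len(y)
        # strict improvement only: ascending grid order implements the
        # smallest-C-then-smallest-gamma tie-break
        if best is None or acc > best[0]:
            best = (acc, C, gamma)

    cv_accuracy, C, gamma = best
    final = SVC(kernel="rbf", C=C, gamma=gamma, cache_size=200,
                decision_function_shape="ovr")
    final.fit(X, y)
    return TrainedClassifier(estimator=final, C=C, gamma=gamma,
                             cv_accuracy=cv_accuracy,
                             classes=tuple(final.classes_), grid=grid)


def classify_detections(image: np.ndarray | CoreImage,
                        detections: list[Detection],
                        model: TrainedClassifier,
                        fill: tuple[int, int, int] = DEFAULT_FILL,
                        ) -> list[ClassifiedSignal]:
    """Assign one of the five classes to every detection, order preserved."""
    if not detections:
        return []
    n_features = model.estimator.n_features_in_
    if n_features != FEATURE_LENGTH:
        raise ValueError(
            f"model expects {n_features} features, patches provide {FEATURE_LENGTH}"
        )
    patches = np.stack([
        extract_patch(image, (d.x, d.y), PATCH_SIZE, fill) for d in detections
    ])
    X = featurize_patches(patches)
    labels = model.predict(X)
    scores = model.decision_scores(X)
    return [
        ClassifiedSignal(detection=d, label=str(lbl), score=float(s))
        for d, lbl, s in zip(detections, labels, scores)
    ]


# ---------------------------------------------------------------------------
# persistence

def save_model(model: TrainedClassifier, path) -> None:
    """Serialize a trained classifier to a single versioned file."""
    joblib.dump({
        "format": "ishprofiler-svm",
        "format_version": MODEL_FORMAT_VERSION,
        "estimator": model.estimator,
        "C": model.C,
        "gamma": model.gamma,
        "cv_accuracy": model.cv_accuracy,
        "classes": model.classes,
        "grid": model.grid,
    }, path)


def load_model(path) -> TrainedClassifier:
    blob = joblib.load(path)
    if blob.get("format") != "ishprofiler-svm":
        raise ValueError(f"{path} is not an ishprofiler model file")
    if blob.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {blob.get('format_version')}"
        )
    return TrainedClassifier(
        estimator=blob["estimator"], C=blob["C"], gamma=blob["gamma"],
        cv_accuracy=blob["cv_accuracy"], classes=tuple(blob["classes"]),
        grid=list(blob["grid"]),
    )


def write_signals(signals: list[ClassifiedSignal], path) -> None:
    """TSV with columns x, y, radius, strength, label, score."""
    pd.DataFrame(
        [(s.detection.x, s.detection.y, s.detection.radius,
          s.detection.strength, s.label, s.score) for s in signals],
        columns=["x", "y", "radius", "strength", "label", "score"],
    ).to_csv(path, sep="\t", index=False)


def read_signals(path) -> list[ClassifiedSignal]:
    df = pd.read_csv(Path(path), sep="\t")
    return [
        ClassifiedSignal(
            detection=Detection(float(r["x"]), float(r["y"]),
                                float(r["radius"]), float(r["strength"])),
            label=str(r["label"]), score=float(r["score"]),
        )
        for _, r in df.iterrows()
    ]
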