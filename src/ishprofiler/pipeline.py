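"""End-to-end convenience drivers: detect -> classify -> quantify for a
single core, and the tiled whole-slide variant with seam deduplication.
"""

from __future__ import annotations

import numpy as np

from .classification import ClassifiedSignal, TrainedClassifier, classify_detections
from .colormap import TileGrid
from .detection import Detection, DetectionParams, detect_circles
from .image_io import CoreImage
from .quantification import CoreResult, QuantConfig, global_ratio, tally_counts

__all__ = ["quantify_core", "detect_slide", "quantify_slide"]


def quantify_core(image: np.ndarray | CoreImage, model: TrainedClassifier,
                  params: DetectionParams | None = None,
                  cfg: QuantConfig | None = None,
                  ) -> tuple[CoreResult, list[ClassifiedSignal]]:
    """Full single-core pipeline: detect, classify, tally, ratio, call."""
    detections = detect_circles(image, params)
    signals = classify_detections(image, detections, model)
    result = global_ratio(tally_counts(signals), cfg)
    return result, signals


def detect_slide(image: np.ndarray, model: TrainedClassifier,
                 tile: int = 2000,
                 params: DetectionParams | None = None,
                 ) -> list[ClassifiedSignal]:
    """Detect and classify over a tiled slide, coordinates in slide frame.

    Tiles are read with a ``2 * radius_max`` overlap margin on their
    right/bottom edges; detections whose centres fall inside the margin
    are suppressed there and recovered by the neighbouring tile, so no
    signal is counted twice across a seam.
    """
    params = params or DetectionParams()
    image = np.asarray(image)
    h, w = image.shape[:2]
    margin = 2 * params.radius_max
    grid = TileGrid(slide_w=w, slide_h=h, tile=tile)
    signals: list[ClassifiedSignal] = []
    for row in range(grid.n_rows):
        for col in range(grid.n_cols):
            y0, x0 = row * tile, col * tile
            y1, x1 = min(h, y0 + tile + margin), min(w, x0 + tile + margin)
            patch = image[y0:y1, x0:x1]
            if min(patch.shape[:2]) < 2 * params.radius_max + 1:
                continue
            detections = detect_circles(patch, params)
            kept = [d for d in detections if d.x < tile and d.y < tile]
            classified = classify_detections(patch, kept, model)
            for s in classified:
                d = s.detection
                signals.append(ClassifiedSignal(
                    detection=Detection(d.x + x0, d.y + y0, d.radius,
                                        d.strength, d.near_border),
                    label=s.label, score=s.score,
                ))
    return signals


def quantify_slide(image: np.ndarray, model: TrainedClassifier,
                   tile: int = 2000,
                   params: DetectionParams | None = None,
                   cfg: QuantConfig | None = None,
                   ) -> tuple[CoreResult, list[ClassifiedSignal]]:
    """Whole-slide global ratio from tiled detection + classification."""
    signals = detect_slide(image, model, tile, params)
    return global_ratio(tally_counts(signals), cfg), signals
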