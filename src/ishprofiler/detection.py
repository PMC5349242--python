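"""Circular-Hough detection of DISH signals.

Signals are dark-on-light roundish dots of radius 1-7 px: black
(silver) gene signals and red centromeric signals.  Both are darker
than the background in luminance, so a single pass over the inverted
luminance channel finds candidates of either colour; colour assignment
happens downstream in the classifier.

Pipeline: gradient-magnitude edge map (Otsu-thresholded by default) ->
Hough accumulator per radius -> per-radius acceptance threshold
``(1 - sensitivity) * max_accumulator`` -> blob-contrast verification
(the candidate disc must be darker than its surrounding annulus, which
rejects the spurious small-radius responses every thin edge curve
produces) -> non-maximum suppression -> sub-pixel centre refinement.

``sensitivity`` keeps its conventional direction: raising it lowers the
acceptance threshold and never decreases the number of detections.  The
defaults are 0.85 for high-resolution scans and 0.95 for the standard
scanner profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.transform import hough_circle

from .image_io import CoreImage

AUTO = "auto"

#: default sensitivity per scanner profile
SENSITIVITY_DEFAULTS = {"high_res": 0.85, "standard": 0.95}

#: default minimum inside-vs-surround contrast (8-bit luminance units) a
#: candidate disc must show; genuine silver/red signals are >~100 units
#: darker than the background, while edge-curve artefacts straddle the
#: boundary and score near zero
MIN_BLOB_CONTRAST = 30.0

__all__ = [
    "AUTO",
    "DetectionParams",
    "Detection",
    "edge_map",
    "detect_circles",
    "write_detections",
    "read_detections",
]


@dataclass(frozen=True)
class DetectionParams:
    """Tunable parameters of the circle detector.

    ``sensitivity=None`` selects the default for the image's scanner
    profile (0.85 high_res, 0.95 standard).  ``edge_threshold=AUTO``
    applies Otsu's method to the gradient-magnitude histogram.
    """

    radius_min: int = 1
    radius_max: int = 7
    sensitivity: float | None = None
    edge_threshold: float | str = AUTO
    min_centre_distance: float = 2.0
    min_contrast: float = MIN_BLOB_CONTRAST

    def __post_init__(self) -> None:
        if not (1 <= self.radius_min <= self.radius_max):
            raise ValueError("require 1 <= radius_min <= radius_max")
        if self.sensitivity is not None and not (0.0 < self.sensitivity <= 1.0):
            raise ValueError("sensitivity must be in (0, 1]")
        if self.min_centre_distance <= 0:
            raise ValueError("min_centre_distance must be > 0")


@dataclass(frozen=True)
class Detection:
    """One candidate circular signal."""

    x: float
    y: float
    radius: float
    strength: float
    near_border: bool = False


def _luminance(pixels: np.ndarray) -> np.ndarray:
    rgb = pixels.astype(np.float64)
    return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]


def _gradient_magnitude(lum: np.ndarray) -> np.ndarray:
    gy = ndimage.sobel(lum, axis=0)
    gx = ndimage.sobel(lum, axis=1)
    return np.hypot(gx, gy)


def edge_map(image: np.ndarray | CoreImage,
             edge_threshold: float | str = AUTO) -> np.ndarray:
    """Binary edge mask from the luminance gradient magnitude.

    In AUTO mode the threshold is Otsu's, computed on the 256-bin
    histogram of gradient magnitudes; a constant image yields an
    all-zero mask.  An explicit threshold marks every pixel whose
    gradient magnitude strictly exceeds it (so 0 marks all nonzero
    gradients).
    """
    pixels = image.pixels if isinstance(image, CoreImage) else np.asarray(image)
    if pixels.ndim == 3:
        lum = _luminance(pixels)
    else:
        lum = pixels.astype(np.float64)
    grad = _gradient_magnitude(lum)
    if isinstance(edge_threshold, str):
        if edge_threshold != AUTO:
            raise ValueError(f"unknown edge_threshold mode {edge_threshold!r}")
        if grad.max() <= 0:
            return np.zeros_like(grad, dtype=bool)
        thr = threshold_otsu(grad, nbins=256)
    else:
        thr = float(edge_threshold)
    return grad > thr


_N_SECTORS = 8


def _ring_masks(radius: int) -> tuple[np.ndarray, list[np.ndarray], int]:
    """Inside-disc mask and angular-sector masks of the surround annulus."""
    outer = radius + 3
    yy, xx = np.mgrid[-outer:outer + 1, -outer:outer + 1]
    d = np.hypot(xx, yy)
    inside = d <= radius
    annulus = (d > radius + 1) & (d <= outer)
    angle = np.arctan2(yy, xx)
    sector_ids = ((angle + math.pi) / (2.0 * math.pi) * _N_SECTORS).astype(int)
    sector_ids = np.clip(sector_ids, 0, _N_SECTORS - 1)
    sectors = [annulus & (sector_ids == k) for k in range(_N_SECTORS)]
    sectors = [s for s in sectors if s.any()]
    return inside, sectors, outer


def _blob_contrasts(inv_lum: np.ndarray, xs: np.ndarray, ys: np.ndarray,
                    radius: int) -> np.ndarray:
    """Worst-case inside-vs-surround contrast of inverted luminance.

    Per candidate: mean inside the disc minus the *darkest* angular
    sector of the surrounding annulus.  A genuine isolated blob is
    lighter all around, so it keeps its full contrast; a candidate on
    or just inside the boundary of a larger dark structure (nucleus,
    bigger signal) has at least one dark sector and scores near or
    below zero.
    """
    inside, sectors, outer = _ring_masks(radius)
    padded = np.pad(inv_lum, outer, mode="edge")
    out = np.empty(len(xs))
    for i, (x, y) in enumerate(zip(xs, ys)):
        window = padded[y:y + 2 * outer + 1, x:x + 2 * outer + 1]
        darkest = max(window[s].mean() for s in sectors)
        out[i] = window[inside].mean() - darkest
    return out


def _refine_centre(acc: np.ndarray, y: int, x: int) -> tuple[float, float]:
    """Sub-pixel centre: intensity centroid of the 3x3 accumulator patch."""
    h, w = acc.shape
    y0, y1 = max(0, y - 1), min(h, y + 2)
    x0, x1 = max(0, x - 1), min(w, x + 2)
    patch = acc[y0:y1, x0:x1]
    total = patch.sum()
    if total <= 0:
        return float(x), float(y)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    return float((patch * xx).sum() / total), float((patch * yy).sum() / total)


def _refine_radius(accs: np.ndarray, ri: int, y: int, x: int,
                   radii: np.ndarray) -> float:
    """Parabolic interpolation of the radius across neighbouring bins."""
    if ri == 0 or ri == len(radii) - 1:
        return float(radii[ri])
    fm, f0, fp = accs[ri - 1, y, x], accs[ri, y, x], accs[ri + 1, y, x]
    denom = fm - 2.0 * f0 + fp
    if denom >= 0:
        return float(radii[ri])
    delta = 0.5 * (fm - fp) / denom
    return float(radii[ri] + np.clip(delta, -0.5, 0.5))


def detect_circles(image: np.ndarray | CoreImage,
                   params: DetectionParams | None = None,
                   ) -> list[Detection]:
    """Detect roundish signals as circles of radius 1-7 px (default).

    Returns detections sorted by descending accumulator strength after
    non-maximum suppression at ``min_centre_distance``.  Detections
    whose centre lies within ``radius_max`` of the image border are
    retained but flagged ``near_border``.
    """
    params = params or DetectionParams()
    if isinstance(image, CoreImage):
        pixels = image.pixels
        profile = image.scanner_profile
    else:
        pixels = np.asarray(image)
        profile = "high_res"
    sensitivity = params.sensitivity
    if sensitivity is None:
        sensitivity = SENSITIVITY_DEFAULTS[profile]

    h, w = pixels.shape[:2]
    min_side = 2 * params.radius_max + 1
    if h < min_side or w < min_side:
        raise ValueError(
            f"image {w}x{h} is smaller than 2*radius_max+1 = {min_side} per side"
        )

    edges = edge_map(pixels, params.edge_threshold)
    if not edges.any():
        return []

    radii = np.arange(params.radius_min, params.radius_max + 1)
    accs = hough_circle(edges, radii, normalize=True)
    inv_lum = 255.0 - _luminance(pixels) if pixels.ndim == 3 \
        else 255.0 - pixels.astype(np.float64)

    # candidate peaks: per-radius local maxima above the sensitivity cut,
    # verified as genuine dark blobs before suppression
    cand_r, cand_y, cand_x, cand_s = [], [], [], []
    for ri, radius in enumerate(radii):
        acc = accs[ri]
        peak = acc.max()
        if peak <= 0:
            continue
        thr = (1.0 - sensitivity) * peak
        local_max = acc == ndimage.maximum_filter(acc, size=3)
        ys, xs = np.nonzero(local_max & (acc >= thr) & (acc > 0))
        if len(ys) == 0:
            continue
        good = _blob_contrasts(inv_lum, xs, ys, int(radius)) >= params.min_contrast
        cand_r.append(np.full(int(good.sum()), ri))
        cand_y.append(ys[good])
        cand_x.append(xs[good])
        cand_s.append(acc[ys[good], xs[good]])
    if not cand_r:
        return []
    cand_r = np.concatenate(cand_r)
    cand_y = np.concatenate(cand_y)
    cand_x = np.concatenate(cand_x)
    cand_s = np.concatenate(cand_s)

    # non-maximum suppression, strongest first: a candidate whose centre
    # lies within a kept circle (or closer than min_centre_distance) is a
    # duplicate response to the same blob
    order = np.argsort(-cand_s, kind="stable")
    kept: list[int] = []
    kept_xyr: list[tuple[float, float, float]] = []
    for i in order:
        x, y = float(cand_x[i]), float(cand_y[i])
        r = float(radii[cand_r[i]])
        suppressed = False
        for kx, ky, kr in kept_xyr:
            d2 = (x - kx) ** 2 + (y - ky) ** 2
            cut = max(params.min_centre_distance, kr, r)
            if d2 < cut * cut:
                suppressed = True
                break
        if suppressed:
            continue
        kept.append(int(i))
        kept_xyr.append((x, y, r))

    # sub-pixel refinement can pull neighbouring integer candidates onto
    # the same blob, so deduplicate once more on the refined centres
    detections: list[Detection] = []
    refined_xyr: list[tuple[float, float, float]] = []
    for i in kept:
        ri, y, x = int(cand_r[i]), int(cand_y[i]), int(cand_x[i])
        cx, cy = _refine_centre(accs[ri], y, x)
        radius = _refine_radius(accs, ri, y, x, radii)
        duplicate = False
        for kx, ky, kr in refined_xyr:
            cut = max(params.min_centre_distance, kr, radius)
            if (cx - kx) ** 2 + (cy - ky) ** 2 < cut * cut:
                duplicate = True
                break
        if duplicate:
            continue
        refined_xyr.append((cx, cy, radius))
        near_border = (
            cx < params.radius_max or cy < params.radius_max
            or cx >= w - params.radius_max or cy >= h - params.radius_max
        )
        detections.append(Detection(x=cx, y=cy, radius=radius,
                                    strength=float(cand_s[i]),
                                    near_border=near_border))
    return detections


def write_detections(detections: list[Detection], path) -> None:
    """Write detections as TSV with columns x, y, radius, strength."""
    pd.DataFrame(
        [(d.x, d.y, d.radius, d.strength, int(d.near_border)) for d in detections],
        columns=["x", "y", "radius", "strength", "near_border"],
    ).to_csv(path, sep="\t", index=False)


def read_detections(path) -> list[Detection]:
    df = pd.read_csv(Path(path), sep="\t")
    return [
        Detection(float(r["x"]), float(r["y"]), float(r["radius"]),
                  float(r["strength"]),
                  bool(int(r.get("near_border", 0))))
        for _, r in df.iterrows()
    ]
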