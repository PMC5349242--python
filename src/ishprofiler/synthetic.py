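"""Synthetic DISH image generator with planted ground truth.

Renders tissue-core-like RGB images: a near-white background, blue/purple
hematoxylin-style nuclei (anti-aliased ellipses), and small roundish
signals -- black discs for the gene probe, red discs for the centromeric
reference, and co-located black+red discs for mixed signals.  Every
planted signal is recorded in a :class:`GroundTruth` table so detection,
classification and quantification can be scored against a known answer.

The generator supports spatially heterogeneous deletion zones: axis-
aligned rectangles with their own gene:centromere ratio, emulating
heterogeneous deletion within one slide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

from .labels import BLUE, CEP10, MIXED, PTEN, WHITE

# soft-edge width of rendered discs, px
EDGE_SIGMA = 0.5
# rejection-sampling attempts per signal before declaring the image full
_MAX_TRIES = 2000

__all__ = [
    "Palette",
    "SyntheticSpec",
    "PlantedSignal",
    "GroundTruth",
    "CapacityError",
    "render_core",
    "render_whole_slide",
    "make_training_patches",
    "write_truth",
    "read_truth",
]


class CapacityError(ValueError):
    """Requested signal count does not fit the image at the minimum
    centre-to-centre separation."""


@dataclass(frozen=True)
class Palette:
    """RGB rendering colours (8-bit).

    Defaults mimic a hematoxylin counterstain with silver (black) and
    red chromogens on a near-white background.
    """

    background: tuple[int, int, int] = (245, 242, 240)
    nucleus: tuple[int, int, int] = (150, 140, 190)
    pten: tuple[int, int, int] = (40, 35, 30)
    cep10: tuple[int, int, int] = (185, 60, 70)

    def __post_init__(self) -> None:
        if not all(p < b for p, b in zip(self.pten, self.background)):
            raise ValueError("PTEN colour must be darker than background in all channels")
        r, g, b = self.cep10
        if not (r > g and r > b):
            raise ValueError("CEP10 red channel must exceed its green and blue channels")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic core/slide.

    ``true_ratio`` may be given instead of ``n_pten``; the planted gene
    count is then ``round(true_ratio * n_cep10)``.  ``deletion_zones``
    is a list of ``((x0, y0, width, height), zone_ratio)`` rectangles
    (half-open, pixel units); each zone is planted independently with
    ``n_cep10`` reference signals and ``round(zone_ratio * n_cep10)``
    gene signals.
    """

    image_side: int = 1024
    n_nuclei: int = 30
    n_pten: int = 50
    n_cep10: int = 100
    n_mixed: int = 0
    radius_range: tuple[int, int] = (1, 7)
    true_ratio: float | None = None
    deletion_zones: list[tuple[tuple[int, int, int, int], float]] = field(default_factory=list)
    noise_sd: float = 5.0
    seed: int = 0
    palette: Palette = field(default_factory=Palette)

    def __post_init__(self) -> None:
        if self.image_side < 64:
            raise ValueError("image_side must be >= 64")
        if min(self.n_nuclei, self.n_pten, self.n_cep10, self.n_mixed) < 0:
            raise ValueError("counts must be >= 0")
        rmin, rmax = self.radius_range
        if not (1 <= rmin <= rmax):
            raise ValueError("radius_range must satisfy 1 <= min <= max")
        if self.true_ratio is not None and self.true_ratio <= 0:
            raise ValueError("true_ratio must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def resolved_counts(self) -> tuple[int, int, int]:
        """(n_pten, n_cep10, n_mixed) after applying ``true_ratio``."""
        n_pten = self.n_pten
        if self.true_ratio is not None:
            n_pten = int(round(self.true_ratio * self.n_cep10))
        return n_pten, self.n_cep10, self.n_mixed


@dataclass(frozen=True)
class PlantedSignal:
    label: str  # PTEN | CEP10 | MIXED
    x: float
    y: float
    radius: int
    zone: int = 0  # 0 = outside any deletion zone; 1..k = zone index


@dataclass
class GroundTruth:
    signals: list[PlantedSignal]
    zone_map: dict[int, float] = field(default_factory=dict)

    def count(self, label: str, zone: int | None = None) -> int:
        return sum(
            1
            for s in self.signals
            if s.label == label and (zone is None or s.zone == zone)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.label, s.x, s.y, s.radius, s.zone) for s in self.signals],
            columns=["class", "x", "y", "radius", "zone"],
        )


# ---------------------------------------------------------------------------
# rasterisation primitives


def _soft_disc(canvas: np.ndarray, cx: float, cy: float, radius: float,
               colour: tuple[int, int, int]) -> None:
    """Alpha-composite a disc with an erf-profiled soft edge onto float canvas."""
    h, w = canvas.shape[:2]
    pad = int(math.ceil(radius + 3 * EDGE_SIGMA + 1))
    x0, x1 = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
    y0, y1 = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(xx - cx, yy - cy)
    alpha = 0.5 * (1.0 + erf((radius - d) / (EDGE_SIGMA * math.sqrt(2.0))))
    region = canvas[y0:y1, x0:x1]
    region += alpha[..., None] * (np.asarray(colour, float) - region)


def _soft_ellipse(canvas: np.ndarray, cx: float, cy: float, a: float, b: float,
                  theta: float, colour: tuple[int, int, int]) -> None:
    """Anti-aliased filled ellipse with semi-axes a >= b, rotated by theta."""
    h, w = canvas.shape[:2]
    pad = int(math.ceil(a + 3))
    x0, x1 = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
    y0, y1 = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    u = (xx - cx) * math.cos(theta) + (yy - cy) * math.sin(theta)
    v = -(xx - cx) * math.sin(theta) + (yy - cy) * math.cos(theta)
    # approximate signed distance to the ellipse boundary, px
    d = (np.hypot(u / a, v / b) - 1.0) * b
    alpha = np.clip(0.5 - d, 0.0, 1.0)
    region = canvas[y0:y1, x0:x1]
    region += alpha[..., None] * (np.asarray(colour, float) - region)


def _render_mixed(canvas: np.ndarray, cx: float, cy: float, radius: float,
                  palette: Palette, rng: np.random.Generator) -> None:
    """Mixed signal: red and black discs co-located, centre offset <= 1 px.

    The red disc carries the full radius; the black disc on top is
    smaller (0.6x, at least 1 px), so both chromogens stay visible in a
    13x13 patch at every radius."""
    phi = rng.uniform(0.0, 2.0 * math.pi)
    _soft_disc(canvas, cx + math.cos(phi), cy + math.sin(phi), radius, palette.cep10)
    _soft_disc(canvas, cx, cy, max(1.0, 0.6 * radius), palette.pten)


# ---------------------------------------------------------------------------
# placement


def _in_zone(x: float, y: float, rect: tuple[int, int, int, int]) -> bool:
    x0, y0, zw, zh = rect
    return x0 <= x < x0 + zw and y0 <= y < y0 + zh


def _sample_positions(rng: np.random.Generator, n: int, w: int, h: int,
                      margin: float, min_sep: float,
                      placed: list[tuple[float, float]],
                      keep_out: list[tuple[float, float, float]],
                      rect: tuple[int, int, int, int] | None,
                      forbidden_rects: list[tuple[int, int, int, int]],
                      ) -> list[tuple[float, float]]:
    """Rejection-sample n centres respecting separation and keep-out discs."""
    out: list[tuple[float, float]] = []
    min_sep2 = min_sep * min_sep
    if rect is None:
        lo_x, hi_x = margin, w - margin
        lo_y, hi_y = margin, h - margin
    else:
        x0, y0, zw, zh = rect
        lo_x, hi_x = max(margin, x0), min(w - margin, x0 + zw)
        lo_y, hi_y = max(margin, y0), min(h - margin, y0 + zh)
    if hi_x <= lo_x or hi_y <= lo_y:
        raise CapacityError("zone rectangle leaves no room for signal placement")
    for _ in range(n):
        for _try in range(_MAX_TRIES):
            x = rng.uniform(lo_x, hi_x)
            y = rng.uniform(lo_y, hi_y)
            if rect is None and any(_in_zone(x, y, fr) for fr in forbidden_rects):
                continue
            if any((x - px) ** 2 + (y - py) ** 2 < min_sep2 for px, py in placed):
                continue
            if any((x - kx) ** 2 + (y - ky) ** 2 < kr * kr for kx, ky, kr in keep_out):
                continue
            placed.append((x, y))
            out.append((x, y))
            break
        else:
            raise CapacityError(
                f"could not place {n} signals in a {w}x{h} image at "
                f"minimum separation {min_sep:.0f} px"
            )
    return out


# ---------------------------------------------------------------------------
# top-level renderers


def _render(spec: SyntheticSpec, width: int, height: int) -> tuple[np.ndarray, GroundTruth]:
    rng = np.random.default_rng(spec.seed)
    pal = spec.palette
    canvas = np.empty((height, width, 3), dtype=np.float64)
    canvas[:] = np.asarray(pal.background, float)

    # nuclei: anti-aliased ellipses with random orientation
    keep_out: list[tuple[float, float, float]] = []
    rmin, rmax = spec.radius_range
    # semi-axes 10-18 px: at 0.11-0.23 um/px real nuclei span tens of
    # pixels, well above the 1-7 px signal scale
    for _ in range(spec.n_nuclei):
        a = rng.uniform(10.0, 18.0)
        b = rng.uniform(7.0, a)
        cx = rng.uniform(a, width - a)
        cy = rng.uniform(a, height - a)
        theta = rng.uniform(0.0, math.pi)
        _soft_ellipse(canvas, cx, cy, a, b, theta, pal.nucleus)
        # signals are planted clear of nuclei so each disc sits on background
        keep_out.append((cx, cy, a + rmax + 3.0))

    n_pten, n_cep10, n_mixed = spec.resolved_counts()
    min_sep = 2.0 * rmax
    margin = rmax + 2.0
    placed: list[tuple[float, float]] = []
    signals: list[PlantedSignal] = []
    zone_map: dict[int, float] = {}

    zone_rects = [rect for rect, _ in spec.deletion_zones]

    def plant(label: str, n: int, zone: int, rect) -> None:
        positions = _sample_positions(
            rng, n, width, height, margin, min_sep, placed, keep_out,
            rect, zone_rects,
        )
        for x, y in positions:
            r = int(rng.integers(rmin, rmax + 1))
            signals.append(PlantedSignal(label, x, y, r, zone))

    # global (outside-zone) signals
    plant(PTEN, n_pten, 0, None)
    plant(CEP10, n_cep10, 0, None)
    plant(MIXED, n_mixed, 0, None)

    # per-zone planting: each zone gets n_cep10 references at its own ratio
    for zi, (rect, zone_ratio) in enumerate(spec.deletion_zones, start=1):
        zone_map[zi] = float(zone_ratio)
        plant(PTEN, int(round(zone_ratio * spec.n_cep10)), zi, rect)
        plant(CEP10, spec.n_cep10, zi, rect)

    for s in signals:
        if s.label == PTEN:
            _soft_disc(canvas, s.x, s.y, s.radius, pal.pten)
        elif s.label == CEP10:
            _soft_disc(canvas, s.x, s.y, s.radius, pal.cep10)
        else:
            _render_mixed(canvas, s.x, s.y, s.radius, pal, rng)

    if spec.noise_sd > 0:
        canvas += rng.normal(0.0, spec.noise_sd, canvas.shape)
    image = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    return image, GroundTruth(signals=signals, zone_map=zone_map)


def render_core(spec: SyntheticSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a square synthetic tissue core.

    Returns an ``(image_side, image_side, 3)`` uint8 RGB image and the
    :class:`GroundTruth` of planted signals.  Deterministic for a fixed
    spec (including seed).

    Raises
    ------
    CapacityError
        If the requested counts cannot be placed at the minimum
        centre separation of twice the maximum radius.
    """
    return _render(spec, spec.image_side, spec.image_side)


def render_whole_slide(spec: SyntheticSpec, slide_w: int, slide_h: int,
                       max_bytes: int = 2 << 30) -> tuple[np.ndarray, GroundTruth]:
    """Render a synthetic whole-slide image of ``slide_w`` x ``slide_h`` px.

    Truth coordinates are in the whole-slide frame.  Slides whose float
    working buffer would exceed ``max_bytes`` are refused with a hint to
    generate tiles instead.
    """
    if slide_w < 64 or slide_h < 64:
        raise ValueError("slide dimensions must be >= 64 px")
    if slide_w * slide_h * 3 * 8 > max_bytes:
        raise MemoryError(
            f"{slide_w}x{slide_h} exceeds the in-memory rendering budget; "
            "generate the slide tile by tile instead"
        )
    return _render(spec, slide_w, slide_h)


# ---------------------------------------------------------------------------
# labelled training patches

PATCH_SIZE = 13


def make_training_patches(spec: SyntheticSpec, n_per_class: int,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Generate labelled 13x13 patches for the five signal classes.

    Each patch has the class-defining content centred: a black disc
    (PTEN), a red disc (CEP10), co-located black+red discs (MIXED), bare
    white background (WHITE), or hematoxylin-blue cell stain (BLUE).

    Returns ``(patches, labels)`` where patches is
    ``(5 * n_per_class, 13, 13, 3)`` uint8 and labels is a string array.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(spec.seed)
    pal = spec.palette
    # training radii match the deployment range; large discs are simply
    # clipped by the 13x13 window, exactly as they are at predict time
    rmin, rmax = spec.radius_range
    centre = (PATCH_SIZE - 1) / 2.0

    patches = []
    labels = []
    for label in (PTEN, CEP10, MIXED, WHITE, BLUE):
        for _ in range(n_per_class):
            patch = np.empty((PATCH_SIZE, PATCH_SIZE, 3), dtype=np.float64)
            patch[:] = np.asarray(pal.background, float)
            if label == BLUE:
                # cell stain fills the patch
                patch[:] = np.asarray(pal.nucleus, float)
            elif label != WHITE:
                r = int(rng.integers(rmin, rmax + 1))
                # +-1.5 px jitter emulates the detector's localization
                # error, so the classifier tolerates off-centre windows
                jx = centre + rng.uniform(-1.5, 1.5)
                jy = centre + rng.uniform(-1.5, 1.5)
                if label == PTEN:
                    _soft_disc(patch, jx, jy, r, pal.pten)
                elif label == CEP10:
                    _soft_disc(patch, jx, jy, r, pal.cep10)
                else:
                    _render_mixed(patch, jx, jy, r, pal, rng)
            if spec.noise_sd > 0:
                patch += rng.normal(0.0, spec.noise_sd, patch.shape)
            patches.append(np.clip(np.rint(patch), 0, 255).astype(np.uint8))
            labels.append(label)
    return np.stack(patches), np.asarray(labels)


# ---------------------------------------------------------------------------
# truth table I/O


def write_truth(truth: GroundTruth, path) -> None:
    """Write the planted-signal table as TSV: class, x, y, radius, zone."""
    truth.to_frame().to_csv(path, sep="\t", index=False)


def write_patch_table(patches: np.ndarray, labels: np.ndarray, path) -> None:
    """Write labelled patches as TSV: label + 507 raw 8-bit values."""
    n = patches.shape[0]
    flat = np.moveaxis(patches, -1, 1).reshape(n, -1)
    df = pd.DataFrame(flat, columns=[f"v{i}" for i in range(flat.shape[1])])
    df.insert(0, "label", labels)
    df.to_csv(path, sep="\t", index=False)


def read_patch_table(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    labels = df["label"].to_numpy(dtype=str)
    flat = df.drop(columns="label").to_numpy(dtype=np.uint8)
    side = int(math.isqrt(flat.shape[1] // 3))
    patches = np.moveaxis(flat.reshape(-1, 3, side, side), 1, -1)
    return patches, labels


def read_truth(path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t")
    signals = [
        PlantedSignal(str(r["class"]), float(r["x"]), float(r["y"]),
                      int(r["radius"]), int(r["zone"]))
        for _, r in df.iterrows()
    ]
    return GroundTruth(signals=signals)
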