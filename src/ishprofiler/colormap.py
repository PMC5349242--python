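"""Signal colour maps and whole-slide tiling.

A signal colour map re-renders each classified signal as a solid marker
at its detected position on a clean background -- black for the gene,
red for the centromeric reference, green for mixed signals -- giving a
position-preserving picture of heterogeneous deletion across a core or
slide.  Whole slides are processed as fixed-size tiles (2,000 px by
default) whose per-tile maps merge into a single deletion landscape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .classification import ClassifiedSignal
from .labels import CEP10, MIXED, PTEN, REJECT_CLASSES

#: default edge length of whole-slide tiles, px
DEFAULT_TILE = 2000

__all__ = [
    "DEFAULT_TILE",
    "MarkerPalette",
    "TileGrid",
    "ColorMap",
    "tile_count",
    "tile_image",
    "render_colormap",
    "merge_colormaps",
]


@dataclass(frozen=True)
class MarkerPalette:
    """Marker colours of the colour map (RGB)."""

    background: tuple[int, int, int] = (255, 255, 255)
    pten: tuple[int, int, int] = (0, 0, 0)  # black
    cep10: tuple[int, int, int] = (220, 0, 0)  # red
    mixed: tuple[int, int, int] = (0, 170, 0)  # green

    def colour_of(self, label: str) -> tuple[int, int, int]:
        return {PTEN: self.pten, CEP10: self.cep10, MIXED: self.mixed}[label]


@dataclass(frozen=True)
class TileGrid:
    """Geometry of a tiled whole slide.

    ``partial_policy`` decides what happens when the slide does not
    divide evenly: ``pad`` fills partial tiles with background,
    ``truncate`` drops the remainder, ``error`` refuses.
    """

    slide_w: int
    slide_h: int
    tile: int = DEFAULT_TILE
    partial_policy: str = "pad"

    def __post_init__(self) -> None:
        if self.slide_w <= 0 or self.slide_h <= 0 or self.tile <= 0:
            raise ValueError("slide dimensions and tile size must be > 0")
        if self.partial_policy not in ("pad", "truncate", "error"):
            raise ValueError("partial_policy must be pad | truncate | error")
        if self.partial_policy == "error" and (
                self.slide_w % self.tile or self.slide_h % self.tile):
            raise ValueError(
                f"slide {self.slide_w}x{self.slide_h} is not divisible by "
                f"tile {self.tile}"
            )

    @property
    def n_cols(self) -> int:
        if self.partial_policy == "truncate":
            return self.slide_w // self.tile
        return math.ceil(self.slide_w / self.tile)

    @property
    def n_rows(self) -> int:
        if self.partial_policy == "truncate":
            return self.slide_h // self.tile
        return math.ceil(self.slide_h / self.tile)

    @property
    def n_tiles(self) -> int:
        return self.n_cols * self.n_rows


def tile_count(slide_w: int, slide_h: int, tile: int = DEFAULT_TILE) -> int:
    """Number of tiles covering a slide: ceil(w/tile) * ceil(h/tile)."""
    if slide_w <= 0 or slide_h <= 0 or tile <= 0:
        raise ValueError("slide dimensions and tile size must be > 0")
    return math.ceil(slide_w / tile) * math.ceil(slide_h / tile)


def tile_image(image: np.ndarray, grid: TileGrid,
               fill: tuple[int, int, int] = (255, 255, 255)):
    """Iterate row-major over ``(tile_row, tile_col, patch)`` tiles.

    Every source pixel lands in exactly one tile.  Under the ``pad``
    policy partial tiles are filled with ``fill``; under ``truncate``
    the remainder rows/columns are skipped.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    if h != grid.slide_h or w != grid.slide_w:
        raise ValueError(
            f"image {w}x{h} does not match grid {grid.slide_w}x{grid.slide_h}"
        )
    t = grid.tile
    for row in range(grid.n_rows):
        for col in range(grid.n_cols):
            y0, x0 = row * t, col * t
            y1, x1 = min(h, y0 + t), min(w, x0 + t)
            patch = image[y0:y1, x0:x1]
            if patch.shape[0] != t or patch.shape[1] != t:
                padded = np.empty((t, t) + image.shape[2:], dtype=image.dtype)
                padded[:] = np.asarray(fill, image.dtype)
                padded[: patch.shape[0], : patch.shape[1]] = patch
                patch = padded
            yield row, col, patch


@dataclass
class ColorMap:
    """A rendered signal colour map plus the signals that produced it."""

    image: np.ndarray
    marker_palette: MarkerPalette = field(default_factory=MarkerPalette)
    marker_radius: int = 3
    signals: list[tuple[str, float, float]] = field(default_factory=list)


def _draw_marker(canvas: np.ndarray, x: float, y: float, radius: int,
                 colour: tuple[int, int, int]) -> None:
    h, w = canvas.shape[:2]
    x0, x1 = max(0, int(x) - radius - 1), min(w, int(x) + radius + 2)
    y0, y1 = max(0, int(y) - radius - 1), min(h, int(y) + radius + 2)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (xx - x) ** 2 + (yy - y) ** 2 <= radius * radius
    canvas[y0:y1, x0:x1][mask] = colour


def _signal_tuples(signals) -> list[tuple[str, float, float]]:
    out = []
    for s in signals:
        if isinstance(s, ClassifiedSignal):
            out.append((s.label, s.detection.x, s.detection.y))
        else:
            label, x, y = s
            out.append((str(label), float(x), float(y)))
    return out


def render_colormap(dims: tuple[int, int], signals,
                    palette: MarkerPalette | None = None,
                    marker_radius: int = 3) -> ColorMap:
    """Render a colour map of ``dims = (width, height)`` pixels.

    White/blue signals are skipped; each retained signal becomes one
    solid marker disc at its position.  Out-of-bounds positions are an
    error listing the offending signal indices.
    """
    palette = palette or MarkerPalette()
    w, h = dims
    if w <= 0 or h <= 0:
        raise ValueError("dims must be positive")
    triples = _signal_tuples(signals)
    bad = [i for i, (_, x, y) in enumerate(triples)
           if not (0 <= x < w and 0 <= y < h)]
    if bad:
        raise ValueError(f"signal position(s) outside {w}x{h} map: indices {bad}")
    canvas = np.empty((h, w, 3), dtype=np.uint8)
    canvas[:] = np.asarray(palette.background, np.uint8)
    kept = [(lbl, x, y) for lbl, x, y in triples if lbl not in REJECT_CLASSES]
    for lbl, x, y in kept:
        _draw_marker(canvas, x, y, marker_radius, palette.colour_of(lbl))
    return ColorMap(image=canvas, marker_palette=palette,
                    marker_radius=marker_radius, signals=kept)


def merge_colormaps(tiles: list[tuple[int, int, ColorMap]],
                    grid: TileGrid) -> ColorMap:
    """Merge per-tile colour maps into one slide-frame landscape.

    Requires the complete tile set of the grid.  Signals are translated
    from tile-local to slide coordinates and re-rendered, so a marker
    crossing a tile boundary is drawn once, seamlessly.
    """
    expected = {(r, c) for r in range(grid.n_rows) for c in range(grid.n_cols)}
    provided = {(r, c) for r, c, _ in tiles}
    missing = sorted(expected - provided)
    if missing:
        raise ValueError(f"missing tile(s) (row, col): {missing}")

    first = tiles[0][2]
    palette = first.marker_palette
    marker_radius = first.marker_radius
    slide_signals: list[tuple[str, float, float]] = []
    for row, col, cmap in tiles:
        dx, dy = col * grid.tile, row * grid.tile
        for lbl, x, y in cmap.signals:
            slide_signals.append((lbl, x + dx, y + dy))
    return render_colormap((grid.slide_w, grid.slide_h), slide_signals,
                           palette, marker_radius)
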