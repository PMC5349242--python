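"""Image and annotation I/O plus tissue-microarray core utilities.

Coordinate convention used package-wide: 0-based, ``x`` = column,
``y`` = row, origin at the top-left, half-open pixel boxes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

#: working side length after preprocessing resize, px (2**12)
WORKING_SIDE = 4096

#: controlled vocabulary for tissue types in annotation files
TISSUE_TYPES = ("BPH", "RPE", "CRPC", "LNM", "DM")

#: deletion labels in annotation files
DELETION_LABELS = ("no_deletion", "deletion")

__all__ = [
    "WORKING_SIDE",
    "TISSUE_TYPES",
    "CoreImage",
    "AnnotationRecord",
    "AnnotationError",
    "read_image",
    "write_image",
    "resize_to_working",
    "read_annotations",
    "write_annotations",
    "generate_core_ids",
]


class AnnotationError(ValueError):
    """Malformed annotation table (missing column or bad value)."""


@dataclass
class CoreImage:
    """An 8-bit RGB tissue-core image with its identifier.

    ``scanner_profile`` distinguishes the high-resolution scanner
    (0.11 um/px) from the standard one (0.23 um/px); the detection
    stage picks its default sensitivity from it.
    """

    pixels: np.ndarray
    source_id: str = ""
    scanner_profile: str = "high_res"  # high_res | standard

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("CoreImage requires an HxWx3 array")
        if px.dtype != np.uint8:
            raise ValueError("CoreImage requires 8-bit pixels")
        if px.size == 0:
            raise ValueError("CoreImage must be non-empty")
        if self.scanner_profile not in ("high_res", "standard"):
            raise ValueError("scanner_profile must be 'high_res' or 'standard'")
        self.pixels = px


@dataclass
class AnnotationRecord:
    """One row of a patient-level annotation table."""

    loc: str
    label: str  # no_deletion | deletion
    tissue_type: str  # BPH | RPE | CRPC | LNM | DM
    dish_manual: float
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in DELETION_LABELS:
            raise AnnotationError(f"unknown deletion label {self.label!r}")
        if self.tissue_type not in TISSUE_TYPES:
            raise AnnotationError(
                f"tissue type {self.tissue_type!r} not in {TISSUE_TYPES}"
            )
        if self.dish_manual < 0:
            raise AnnotationError("dish_manual ratio must be >= 0")


def read_image(path, source_id: str | None = None,
               scanner_profile: str = "high_res") -> CoreImage:
    """Read a JPEG/PNG/TIFF image as 8-bit RGB.

    Grayscale images are promoted to three channels and alpha channels
    dropped; bit depths other than 8 are rejected.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            if im.mode in ("I;16", "I;16B", "I;16L", "I", "F"):
                raise ValueError(f"unsupported bit depth in {path}: mode {im.mode}")
            if im.mode != "RGB":
                im = im.convert("RGB")
            pixels = np.asarray(im, dtype=np.uint8)
    except FileNotFoundError:
        raise
    except (OSError, SyntaxError) as exc:
        raise OSError(f"cannot decode image file {path}: {exc}") from exc
    if source_id is None:
        # e.g. "A_1_1_PTEN_Zeiss_4096.jpg" -> "A_1_1"
        m = re.match(r"([A-Za-z]+_\d+_\d+)", path.stem)
        source_id = m.group(1) if m else path.stem
    return CoreImage(pixels=pixels, source_id=source_id,
                     scanner_profile=scanner_profile)


def write_image(image: np.ndarray | CoreImage, path, quality: int = 95) -> None:
    """Write an RGB array as PNG (lossless) or JPEG (with ``quality``)."""
    pixels = image.pixels if isinstance(image, CoreImage) else np.asarray(image)
    im = Image.fromarray(pixels.astype(np.uint8), mode="RGB")
    path = Path(path)
    if path.suffix.lower() in (".jpg", ".jpeg"):
        im.save(path, quality=quality)
    else:
        im.save(path)


def resize_to_working(image: np.ndarray | CoreImage, side: int = WORKING_SIDE,
                      ) -> np.ndarray:
    """Resize to a ``side`` x ``side`` square by bicubic interpolation.

    The target is square regardless of the input aspect ratio; an input
    already at the target size is returned unchanged (identity), which
    makes the operation idempotent.
    """
    if side < 1:
        raise ValueError("side must be >= 1")
    pixels = image.pixels if isinstance(image, CoreImage) else np.asarray(image)
    if pixels.size == 0:
        raise ValueError("cannot resize an empty image")
    if pixels.shape[0] == side and pixels.shape[1] == side:
        return pixels.copy()
    im = Image.fromarray(pixels.astype(np.uint8))
    out = im.resize((side, side), resample=Image.Resampling.BICUBIC)
    return np.asarray(out, dtype=np.uint8)


# ---------------------------------------------------------------------------
# annotation tables

_MANDATORY = {"loc": "loc", "label": "label", "type": "tissue_type",
              "dish_manual": "dish_manual"}

_LABEL_ALIASES = {
    "deletion": "deletion",
    "no deletion": "no_deletion",
    "no_deletion": "no_deletion",
}


def read_annotations(path) -> list[AnnotationRecord]:
    """Read a patient-level annotation table (CSV or TSV).

    The header must contain ``Loc``, ``label``, ``type`` and
    ``DISH_Manual`` (case-insensitive); extra columns are preserved in
    ``AnnotationRecord.extra``.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep, skipinitialspace=True)
    colmap = {c.lower().strip(): c for c in df.columns}
    missing = [k for k in _MANDATORY if k not in colmap]
    if missing:
        raise AnnotationError(
            f"annotation file {path} is missing mandatory column(s): "
            + ", ".join(sorted(missing))
        )
    extra_cols = [c for c in df.columns
                  if c.lower().strip() not in _MANDATORY]
    records = []
    for i, row in df.iterrows():
        raw_label = str(row[colmap["label"]]).strip().lower()
        label = _LABEL_ALIASES.get(raw_label)
        if label is None:
            raise AnnotationError(f"row {i}: unknown deletion label {raw_label!r}")
        tissue = str(row[colmap["type"]]).strip().upper()
        try:
            ratio = float(row[colmap["dish_manual"]])
        except (TypeError, ValueError) as exc:
            raise AnnotationError(
                f"row {i}: unparseable DISH_Manual ratio "
                f"{row[colmap['dish_manual']]!r}"
            ) from exc
        try:
            rec = AnnotationRecord(
                loc=str(row[colmap["loc"]]).strip(),
                label=label,
                tissue_type=tissue,
                dish_manual=ratio,
                extra={c: row[c] for c in extra_cols},
            )
        except AnnotationError as exc:
            raise AnnotationError(f"row {i}: {exc}") from exc
        records.append(rec)
    return records


def write_annotations(records: list[AnnotationRecord], path) -> None:
    """Write annotation records as CSV/TSV (inverse of read_annotations)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    rows = [
        {"Loc": r.loc, "label": r.label, "type": r.tissue_type,
         "DISH_Manual": r.dish_manual, **r.extra}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def generate_core_ids(blocks: list[str], cols: int, rows: int) -> list[str]:
    """Enumerate TMA core identifiers ``<block>_<col>_<row>``.

    Left-to-right within one physical row runs through the columns of
    each block and then crosses into the next block; top-to-bottom
    increments the row index last, e.g. A_1_1, A_2_1, ..., A_8_1,
    B_1_1, ..., then A_1_2, ...
    """
    if not blocks:
        raise ValueError("blocks must be non-empty")
    if cols < 1 or rows < 1:
        raise ValueError("cols and rows must be >= 1")
    return [
        f"{block}_{col}_{row}"
        for row in range(1, rows + 1)
        for block in blocks
        for col in range(1, cols + 1)
    ]
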