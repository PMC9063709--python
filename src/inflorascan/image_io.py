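"""Raster and table I/O, scale calibration, edit-mask algebra and composites.

Every photograph carries its own cm-per-pixel scale (the physical edge length
of one square pixel), supplied by the user at load time.  All downstream
absolute measurements derive from that single number, so it is validated here
and travels with the raster in a :class:`CalibratedImage`.

Coordinate convention: ``x`` is the column index, ``y`` the row index, origin
at the top-left corner, pixel centers at integer coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, ImageOps


class ImageFormatError(ValueError):
    """Raised when an input file cannot be decoded as the expected raster."""


@dataclass(frozen=True)
class CalibratedImage:
    """An 8-bit RGB raster together with its cm-per-pixel scale.

    Parameters
    ----------
    pixels:
        ``(rows, cols, 3)`` uint8 array.
    cm_per_pixel:
        Physical edge length of one (square) pixel, in centimeters.
    image_id:
        Free-text identifier, usually the file stem.
    """

    pixels: np.ndarray
    cm_per_pixel: float
    image_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ImageFormatError("expected 3-channel image")
        if px.dtype != np.uint8:
            raise ImageFormatError("expected 8-bit image")
        if px.shape[0] == 0 or px.shape[1] == 0:
            raise ImageFormatError("empty raster")
        if not (self.cm_per_pixel > 0 and math.isfinite(self.cm_per_pixel)):
            raise ValueError("cm_per_pixel must be a positive finite number")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of the raster."""
        return self.pixels.shape[:2]


def load_image(path: str | Path, cm_per_pixel: float, image_id: str | None = None) -> CalibratedImage:
    """Load an 8-bit RGB photograph and attach its scale calibration.

    EXIF orientation is applied before any measurement, so rasters are always
    in display orientation.  Single-channel (grayscale) or paletted files are
    rejected: the segmentation stage needs the blue band of a true RGB image.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im = ImageOps.exif_transpose(im)
            if im.mode != "RGB":
                raise ImageFormatError(
                    f"expected 3-channel image, got mode {im.mode!r} in {path.name}"
                )
            pixels = np.asarray(im, dtype=np.uint8)
    except ImageFormatError:
        raise
    except Exception as exc:  # decoding failure
        raise ImageFormatError(f"cannot decode {path}: {exc}") from exc
    return CalibratedImage(pixels, float(cm_per_pixel), image_id or path.stem)


def save_image(image: CalibratedImage | np.ndarray, path: str | Path) -> None:
    """Write an RGB raster (or the raster of a CalibratedImage) as PNG/TIFF."""
    px = image.pixels if isinstance(image, CalibratedImage) else np.asarray(image)
    Image.fromarray(px).save(Path(path))


def load_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel mask PNG (0 = background, 255 = object) as boolean."""
    with Image.open(Path(path)) as im:
        if im.mode != "L":
            im = im.convert("L")
        arr = np.asarray(im)
    return arr > 127


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as a single-channel PNG (0/255)."""
    mask = np.asarray(mask, dtype=bool)
    Image.fromarray((mask * np.uint8(255))).save(Path(path))


def apply_edit_mask(mask: np.ndarray, remove: np.ndarray, add: np.ndarray) -> np.ndarray:
    """Apply manual corrections to a binary mask.

    The output is ``(mask AND NOT remove) OR add`` — the mask-algebra
    equivalent of manually erasing undesired objects (tags, scale remnants,
    shading) and painting back missed material.
    """
    mask = np.asarray(mask, dtype=bool)
    remove = np.asarray(remove, dtype=bool)
    add = np.asarray(add, dtype=bool)
    if mask.shape != remove.shape or mask.shape != add.shape:
        raise ValueError(
            f"edit masks must share the source shape {mask.shape}; "
            f"got remove {remove.shape}, add {add.shape}"
        )
    return (mask & ~remove) | add


@dataclass(frozen=True)
class CompositeTile:
    """Placement of one object in a composite montage (for testing/inspection)."""

    object_index: int
    pixel_count: int
    row: int
    col: int


def build_composite(
    objects: list[np.ndarray], pad: int = 4
) -> tuple[np.ndarray, list[CompositeTile]]:
    """Tile object masks into one montage, sorted by surface size.

    Each entry of ``objects`` is a boolean 2-D array containing a single
    object (any shape; it is cropped to its bounding box here).  Tiles are
    laid out left-to-right, top-to-bottom in non-increasing pixel-count
    order; equal-sized objects keep their input order (stable sort).

    Returns the montage as a uint8 raster (0 background, 255 object) and the
    tile placements in montage order.
    """
    if len(objects) == 0:
        raise ValueError("composite requires at least one object")
    if pad < 0:
        raise ValueError("pad must be non-negative")

    crops: list[np.ndarray] = []
    counts: list[int] = []
    for obj in objects:
        obj = np.asarray(obj, dtype=bool)
        rows, cols = np.nonzero(obj)
        if rows.size == 0:
            raise ValueError("composite objects must be non-empty")
        crops.append(obj[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1])
        counts.append(int(rows.size))

    order = sorted(range(len(crops)), key=lambda i: -counts[i])  # stable
    cell_h = max(c.shape[0] for c in crops) + 2 * pad
    cell_w = max(c.shape[1] for c in crops) + 2 * pad
    ncols = max(1, math.ceil(math.sqrt(len(crops))))
    nrows = math.ceil(len(crops) / ncols)

    canvas = np.zeros((nrows * cell_h, ncols * cell_w), dtype=np.uint8)
    tiles: list[CompositeTile] = []
    for slot, idx in enumerate(order):
        r, c = divmod(slot, ncols)
        crop = crops[idx]
        r0 = r * cell_h + pad
        c0 = c * cell_w + pad
        canvas[r0 : r0 + crop.shape[0], c0 : c0 + crop.shape[1]][crop] = 255
        tiles.append(CompositeTile(idx, counts[idx], r0, c0))
    return canvas, tiles
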