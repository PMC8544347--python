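"""Image and table I/O, grayscale conversion and QC overlays.

All pipelines consume RGB micrographs as :class:`MultichannelImage` and
produce per-object tables written as CSV.  The grayscale conversion used
throughout the package is the ITU-R BT.601 luma transform

    gray = 0.2989 R + 0.5870 G + 0.1140 B

applied to raw (unrescaled) intensities, so 16-bit images keep their native
range.  Images are indexed ``(row, col)`` with row 0 at the top; all
geometry is 0-based and half-open.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import ContractError, FormatError

logger = logging.getLogger(__name__)

#: BT.601 luma weights (R, G, B).  Their sum is 0.9999, i.e. within 1e-4 of
#: unity; a uniform gray pixel of value v maps to 0.9999 * v.
LUMA_WEIGHTS = (0.2989, 0.5870, 0.1140)

#: Default physical pixel size of the fluorescence camera, in nm/pixel.
DEFAULT_PIXEL_SIZE_NM = 52.0

#: Named overlay colors (8-bit RGB); scaled up for 16-bit images.
OVERLAY_COLORS = {
    "green": (0, 255, 0),
    "red": (255, 0, 0),
    "yellow": (255, 255, 0),
    "cyan": (0, 255, 255),
}


@dataclass
class MultichannelImage:
    """A 2-D RGB raster with physical pixel size and bit depth.

    ``pixels`` has shape ``(rows, cols, 3)`` and an unsigned integer dtype;
    every intensity must lie in ``[0, 2**bit_depth - 1]``.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    image_id: str = ""

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ContractError(
                f"expected (rows, cols, 3) pixel array, got shape {p.shape}"
            )
        if p.shape[0] < 2 or p.shape[1] < 2:
            raise ContractError(f"image must be at least 2x2, got {p.shape[:2]}")
        if self.bit_depth not in (8, 16):
            raise ContractError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixel_size_nm <= 0:
            raise ContractError("pixel_size_nm must be positive")
        lim = 2**self.bit_depth - 1
        if p.min() < 0 or p.max() > lim:
            raise ContractError(
                f"intensities outside [0, {lim}] for bit depth {self.bit_depth}"
            )
        self.pixels = p

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def channel(self, index: int) -> "GrayImage":
        """Return one raw channel (0=R, 1=G, 2=B) as a float GrayImage."""
        return GrayImage(self.pixels[:, :, index].astype(np.float64), "raw_channel")

    def copy(self) -> "MultichannelImage":
        return MultichannelImage(
            self.pixels.copy(), self.bit_depth, self.pixel_size_nm, self.image_id
        )


@dataclass
class GrayImage:
    """A single-channel real-valued raster derived from an RGB image."""

    pixels: np.ndarray
    provenance: str = "derived_signal"  # raw_channel|grayscale|filtered|derived_signal

    def __post_init__(self):
        p = np.asarray(self.pixels, dtype=np.float64)
        if p.ndim != 2:
            raise ContractError(f"expected 2-D gray array, got shape {p.shape}")
        self.pixels = p

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _dtype_for_depth(bit_depth: int):
    return np.uint8 if bit_depth == 8 else np.uint16


def read_rgb_image(path) -> MultichannelImage:
    """Read a TIFF or PNG micrograph into a :class:`MultichannelImage`.

    Single-channel files are accepted and replicated into three equal
    channels (with a warning).  Files with more than three channels are
    rejected.  ``pixel_size_nm`` is taken from an embedded JSON description
    (key ``pixel_size_nm``, written by :func:`write_rgb_image`) when present,
    otherwise the camera default of 52 nm/px is assumed.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    pixel_size = DEFAULT_PIXEL_SIZE_NM
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            with tifffile.TiffFile(path) as tf:
                arr = tf.asarray()
                desc = tf.pages[0].description
            if desc:
                try:
                    meta = json.loads(desc)
                    pixel_size = float(meta.get("pixel_size_nm", pixel_size))
                except (ValueError, TypeError):
                    pass
        else:
            arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - normalize to I/O error
        raise IOError(f"could not read image {path}: {exc}") from exc

    arr = np.asarray(arr)
    if arr.ndim == 2:
        warnings.warn(
            f"{path.name}: single-channel image replicated into 3 equal channels",
            stacklevel=2,
        )
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3:
        raise FormatError(f"{path.name}: unsupported array shape {arr.shape}")
    if arr.shape[2] != 3:
        raise FormatError(
            f"{path.name}: expected 3 channels, found {arr.shape[2]}"
        )
    bit_depth = 16 if arr.dtype.itemsize > 1 else 8
    return MultichannelImage(
        arr.astype(_dtype_for_depth(bit_depth)),
        bit_depth=bit_depth,
        pixel_size_nm=pixel_size,
        image_id=path.stem,
    )


def write_rgb_image(img: MultichannelImage, path) -> None:
    """Write an image as TIFF (with pixel-size metadata) or PNG."""
    path = Path(path)
    arr = img.pixels.astype(_dtype_for_depth(img.bit_depth))
    if img.bit_depth == 16 and path.suffix.lower() == ".png":
        # no 48-bit RGB PNG mode in the PNG writer; TIFF is the 16-bit format
        raise IOError(f"16-bit RGB images must be written as TIFF, not {path.suffix}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            desc = json.dumps({"pixel_size_nm": img.pixel_size_nm})
            tifffile.imwrite(path, arr, description=desc)
        else:
            iio.imwrite(path, arr)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"could not write image {path}: {exc}") from exc


def to_grayscale(img: MultichannelImage) -> GrayImage:
    """BT.601 luma conversion; values stay real (no rounding)."""
    return gray_of_rgb(img.pixels.astype(np.float64))


def gray_of_rgb(rgb: np.ndarray) -> GrayImage:
    """Luma conversion of a float (rows, cols, 3) array."""
    wr, wg, wb = LUMA_WEIGHTS
    g = wr * rgb[:, :, 0] + wg * rgb[:, :, 1] + wb * rgb[:, :, 2]
    return GrayImage(g, "grayscale")


# ---------------------------------------------------------------------------
# tabular output


def write_region_csv(records: Sequence, path, image_id: str | None = None) -> None:
    """Write RegionRecord or CellClassification rows as CSV, sorted by label.

    The header is ``image_id,cell_id,centroid_row,centroid_col,area_px,
    perimeter_px,total_intensity`` with an extra ``cell_class`` column when
    the records carry a classification.
    """
    rows = []
    has_class = False
    for rec in records:
        region = getattr(rec, "region", rec)
        row = {
            "image_id": image_id or "",
            "cell_id": region.label,
            "centroid_row": region.centroid[0],
            "centroid_col": region.centroid[1],
            "area_px": region.area_px,
            "perimeter_px": region.perimeter_px,
            "total_intensity": region.total_intensity,
        }
        if hasattr(rec, "cell_class"):
            row["cell_class"] = rec.cell_class
            has_class = True
        rows.append(row)
    cols = [
        "image_id",
        "cell_id",
        "centroid_row",
        "centroid_col",
        "area_px",
        "perimeter_px",
        "total_intensity",
    ]
    if has_class:
        cols.append("cell_class")
    frame = pd.DataFrame(rows, columns=cols)
    if len(frame):
        frame = frame.sort_values("cell_id", kind="stable")
    write_csv(frame, path)


def write_csv(frame: pd.DataFrame, path) -> None:
    """Write a DataFrame as comma-separated UTF-8 CSV with header."""
    try:
        frame.to_csv(path, index=False, encoding="utf-8")
    except OSError as exc:
        raise IOError(f"could not write CSV {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# QC overlays


def mask_outlines(mask: np.ndarray, connectivity: int = 8) -> list[np.ndarray]:
    """Per-component 1-px inner boundaries of a boolean mask.

    Returns one ``(n, 2)`` array of (row, col) coordinates per connected
    component, in label order.  A member pixel is boundary if any of its
    4-neighbours (or the image border) is outside the component.
    """
    from scipy import ndimage as ndi

    struct = np.ones((3, 3), bool) if connectivity == 8 else ndi.generate_binary_structure(2, 1)
    labels, n = ndi.label(mask, structure=struct)
    outlines = []
    for lab in range(1, n + 1):
        comp = labels == lab
        interior = ndi.binary_erosion(comp, structure=ndi.generate_binary_structure(2, 1), border_value=0)
        outlines.append(np.argwhere(comp & ~interior))
    return outlines


#: 3x5 bitmap glyphs for integer labels on QC overlays.
_DIGITS = {
    "0": ["111", "101", "101", "101", "111"],
    "1": ["010", "110", "010", "010", "111"],
    "2": ["111", "001", "111", "100", "111"],
    "3": ["111", "001", "111", "001", "111"],
    "4": ["101", "101", "111", "001", "001"],
    "5": ["111", "100", "111", "001", "111"],
    "6": ["111", "100", "111", "101", "111"],
    "7": ["111", "001", "010", "010", "010"],
    "8": ["111", "101", "111", "101", "111"],
    "9": ["111", "101", "111", "001", "111"],
}


def draw_label(pixels: np.ndarray, text: str, pos: tuple[int, int], color) -> None:
    """Stamp an integer label (digits only) onto an RGB pixel array in place.

    ``pos`` is the (row, col) of the glyph block's top-left corner; glyphs
    are 3x5 px with a 1-px gap.  Out-of-bounds portions are clipped.
    """
    h, w = pixels.shape[:2]
    r0, c0 = pos
    for ch in str(text):
        glyph = _DIGITS.get(ch)
        if glyph is None:
            c0 += 4
            continue
        for dr, rowbits in enumerate(glyph):
            for dc, bit in enumerate(rowbits):
                if bit == "1" and 0 <= r0 + dr < h and 0 <= c0 + dc < w:
                    pixels[r0 + dr, c0 + dc] = color
        c0 += 4


def render_overlay(
    img: MultichannelImage,
    contours: Iterable[np.ndarray],
    colors: Iterable,
) -> MultichannelImage:
    """Draw 1-px contours onto a copy of the image.

    ``colors`` holds one entry per contour: a name from
    :data:`OVERLAY_COLORS` (``"green"`` = accepted, ``"red"`` = discarded) or
    an explicit RGB triple.  Contours are drawn in list order; later entries
    overwrite earlier ones where they overlap.  Pixels off the contour set
    are never altered.
    """
    out = img.copy()
    h, w = out.shape
    scale = 1 if img.bit_depth == 8 else 257  # map 8-bit tags onto 16-bit range
    for contour, color in zip(contours, colors):
        contour = np.asarray(contour)
        if contour.size == 0:
            continue
        if contour.ndim != 2 or contour.shape[1] != 2:
            raise ContractError(f"contour must be (n, 2), got {contour.shape}")
        if (
            contour[:, 0].min() < 0
            or contour[:, 1].min() < 0
            or contour[:, 0].max() >= h
            or contour[:, 1].max() >= w
        ):
            raise ContractError("contour outline lies outside image bounds")
        rgb = OVERLAY_COLORS[color] if isinstance(color, str) else tuple(color)
        out.pixels[contour[:, 0], contour[:, 1]] = np.array(rgb) * scale
    return out
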