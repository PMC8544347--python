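"""Membrane-integrity classification from a dual-stain (DAPI/EB) image.

DAPI crosses intact membranes and stains every cell blue; ethidium bromide
(EB) enters only membrane-compromised cells and stains them red.  Both
stains are excited together (UV filter block) and captured in one RGB
frame, so classification reduces to channel arithmetic:

* every channel is background-suppressed with a non-flat top-hat
  (ellipsoid structuring element, radius 60 px, height 5);
* EB signal   = max(0, gray(filtered) - B_filtered)
* DAPI signal = max(0, gray(filtered) - R_filtered)

EB-stained cells bleed into the blue channel (the reverse never happens),
so the EB ("red") mask takes priority: the 3-px-dilated red mask is
subtracted from the blue mask, and a cell visible in both signals is
counted as membrane-damaged only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError
from .imgio import GrayImage, MultichannelImage, gray_of_rgb
from .morphops import (
    BinaryMask,
    RegionRecord,
    StructuringElement,
    binarize,
    clean_mask,
    dilate_mask,
    filter_regions,
    measure_regions,
    otsu_threshold,
    tophat,
)

logger = logging.getLogger(__name__)

CLASS_INTACT = "intact_dapi"
CLASS_DAMAGED = "damaged_eb"


@dataclass
class MembraneConfig:
    """Pipeline constants; defaults are the published processing values."""

    se_radius_px: int = 60
    se_height: float = 5.0
    min_clean_area_px: int = 300
    dilation_radius_px: int = 3
    min_area_px: int = 400
    max_area_px: int = 2000
    max_perimeter_px: float = 250.0
    connectivity: int = 8
    tophat_method: str = "auto"

    def __post_init__(self):
        if min(self.se_radius_px, self.se_height, self.min_clean_area_px,
               self.dilation_radius_px, self.min_area_px, self.max_area_px,
               self.max_perimeter_px) <= 0:
            raise ContractError("all membrane config values must be positive")
        if self.min_clean_area_px > self.min_area_px:
            raise ContractError("min_clean_area_px must be <= min_area_px")

    @property
    def se(self) -> StructuringElement:
        return StructuringElement("ellipsoid", self.se_radius_px, self.se_height)


@dataclass
class CellClassification:
    region: RegionRecord
    cell_class: str  # CLASS_INTACT | CLASS_DAMAGED


@dataclass
class MembraneResult:
    cells: list[CellClassification]
    n_intact: int
    n_damaged: int
    damaged_fraction: float
    n_discarded: int = 0
    red_mask: BinaryMask | None = None
    blue_mask: BinaryMask | None = None

    def to_frame(self, image_id: str = "") -> pd.DataFrame:
        rows = [
            {
                "image_id": image_id,
                "cell_id": i + 1,
                "cell_class": c.cell_class,
                "centroid_row": c.region.centroid[0],
                "centroid_col": c.region.centroid[1],
                "area_px": c.region.area_px,
                "perimeter_px": c.region.perimeter_px,
            }
            for i, c in enumerate(self.cells)
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "image_id",
                "cell_id",
                "cell_class",
                "centroid_row",
                "centroid_col",
                "area_px",
                "perimeter_px",
            ],
        )


def tophat_rgb(img: MultichannelImage, cfg: MembraneConfig) -> np.ndarray:
    """Channel-wise non-flat top-hat of the color image (float array)."""
    out = np.empty(img.pixels.shape, dtype=np.float64)
    for c in range(3):
        # float32 is lossless for integer camera intensities and halves the
        # memory traffic of the large-SE opening
        out[:, :, c] = tophat(
            img.pixels[:, :, c].astype(np.float32), cfg.se, method=cfg.tophat_method
        ).pixels
    return out


def derive_stain_signals(
    img: MultichannelImage, cfg: MembraneConfig | None = None
) -> tuple[GrayImage, GrayImage]:
    """(EB, DAPI) signal images from one dual-stain RGB frame.

    Both are non-negative by construction: eb = max(0, gray - B_filtered),
    dapi = max(0, gray - R_filtered), where gray is the luma of the
    top-hat-filtered color image.
    """
    cfg = cfg or MembraneConfig()
    filt = tophat_rgb(img, cfg)
    gray = gray_of_rgb(filt).pixels
    eb = np.maximum(0.0, gray - filt[:, :, 2])
    dapi = np.maximum(0.0, gray - filt[:, :, 0])
    return GrayImage(eb, "derived_signal"), GrayImage(dapi, "derived_signal")


def build_masks(
    eb: GrayImage, dapi: GrayImage, cfg: MembraneConfig | None = None
) -> tuple[BinaryMask, BinaryMask]:
    """Threshold, clean and de-duplicate the stain signals.

    Each signal gets its own Otsu threshold (an identically-zero signal
    yields an empty mask).  Both masks drop edge-touching components and
    components below ``min_clean_area_px``.  The blue (DAPI) mask then loses
    every pixel of the 3-px-dilated red mask, and any blue fragment pushed
    below the cleanup area by that subtraction is removed, so one physical
    cell can never be counted in both masks.
    """
    cfg = cfg or MembraneConfig()
    if eb.shape != dapi.shape:
        raise ContractError("EB and DAPI signals must share one shape")

    def _signal_mask(sig: GrayImage) -> BinaryMask:
        if sig.pixels.max() == sig.pixels.min():
            return BinaryMask(np.zeros(sig.shape, dtype=bool), cfg.connectivity)
        thr = otsu_threshold(sig)
        m = binarize(sig, thr, cfg.connectivity)
        return clean_mask(m, cfg.min_clean_area_px, remove_edge=True)

    red = _signal_mask(eb)
    blue = _signal_mask(dapi)
    red_grown = dilate_mask(red, cfg.dilation_radius_px)
    blue = BinaryMask(blue.pixels & ~red_grown.pixels, cfg.connectivity)
    # subtraction can leave sub-threshold specks; re-apply the area cleanup
    blue = clean_mask(blue, cfg.min_clean_area_px, remove_edge=False)
    return red, blue


def classify_cells(
    img: MultichannelImage, cfg: MembraneConfig | None = None
) -> MembraneResult:
    """Full membrane pipeline: signals -> masks -> measurement -> gating."""
    cfg = cfg or MembraneConfig()
    eb, dapi = derive_stain_signals(img, cfg)
    red, blue = build_masks(eb, dapi, cfg)

    cells: list[CellClassification] = []
    n_discarded = 0
    for mask, cls in ((red, CLASS_DAMAGED), (blue, CLASS_INTACT)):
        records = measure_regions(mask)
        kept, discarded = filter_regions(
            records, cfg.min_area_px, cfg.max_area_px, cfg.max_perimeter_px
        )
        n_discarded += len(discarded)
        logger.info(
            "%s mask: %d objects, %d kept, %d discarded",
            cls, len(records), len(kept), len(discarded),
        )
        cells.extend(CellClassification(rec, cls) for rec in kept)

    n_damaged = sum(1 for c in cells if c.cell_class == CLASS_DAMAGED)
    n_intact = len(cells) - n_damaged
    frac = n_damaged / max(1, n_intact + n_damaged)
    return MembraneResult(
        cells=cells,
        n_intact=n_intact,
        n_damaged=n_damaged,
        damaged_fraction=frac,
        n_discarded=n_discarded,
        red_mask=red,
        blue_mask=blue,
    )
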