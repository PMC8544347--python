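"""Nucleoid-condensation morphometry.

Several toxins condense the bacterial chromosome into a compact bright
focus.  The pipeline segments bright nucleoid regions from the
background-corrected grayscale image with the extended-maxima operator
(prominence h = 30, 8-connectivity), gates them by area [50, 2000] px and
perimeter <= 250 px, and reports per-object shape descriptors:

* circularity = 4 pi area / perimeter^2 (1 for a disk, smaller otherwise);
* eccentricity of the ellipse with equal second central moments (0 for a
  disk, -> 1 for a line).

Condensed nucleoids are small, round, low-eccentricity objects; diffuse
(relaxed) nucleoids are larger and elongated along the cell axis.

Interactive deletion of mis-identified objects is replaced by a
reproducible exclusion list: records stay in the output with an
``excluded`` flag, and the QC overlay draws each label at its centroid so a
human can curate the list.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure as skmeasure

from .errors import ContractError
from .imgio import MultichannelImage, gray_of_rgb
from .membrane import MembraneConfig, tophat_rgb
from .morphops import (
    BinaryMask,
    RegionRecord,
    clean_mask,
    extended_maxima,
    filter_regions,
    measure_regions,
    _conn_structure,
)

logger = logging.getLogger(__name__)


@dataclass
class NucleoidConfig:
    """Pipeline constants; defaults are the published processing values."""

    h: float = 30.0
    connectivity: int = 8
    min_area_px: int = 50
    max_area_px: int = 2000
    max_perimeter_px: float = 250.0

    def __post_init__(self):
        if self.h <= 0:
            raise ContractError("h must be > 0")
        if self.connectivity not in (4, 8):
            raise ContractError("connectivity must be 4 or 8")


@dataclass
class NucleoidRecord:
    region: RegionRecord
    circularity: float
    eccentricity: float
    excluded: bool = False


def shape_descriptors(region: RegionRecord, mask: BinaryMask) -> tuple[float, float]:
    """(circularity, eccentricity) of one region given its pixel mask.

    Requires >= 5 member pixels.  A degenerate (collinear) region reports
    eccentricity ``1 - 1e-9`` with a warning.
    """
    if region.area_px < 5:
        raise ContractError("shape descriptors need a region of >= 5 pixels")
    circ = 4.0 * math.pi * region.area_px / region.perimeter_px**2 if region.perimeter_px > 0 else math.inf
    props = skmeasure.regionprops(mask.pixels.astype(np.uint8))
    if not props:
        raise ContractError("mask holds no pixels for the region")
    ecc = float(props[0].eccentricity)
    if ecc >= 1.0:
        warnings.warn("degenerate (collinear) region; eccentricity clipped", stacklevel=2)
        ecc = 1.0 - 1e-9
    return float(circ), ecc


def segment_nucleoids(
    img: MultichannelImage,
    mcfg: MembraneConfig | None = None,
    ncfg: NucleoidConfig | None = None,
) -> list[NucleoidRecord]:
    """Segment bright nucleoid regions and measure their shapes.

    Background correction reuses the membrane pipeline's top-hat (same
    ellipsoid SE); the corrected color image is converted to grayscale and
    segmented by extended maxima.  Edge-touching components and components
    outside the area/perimeter window are discarded.
    """
    mcfg = mcfg or MembraneConfig()
    ncfg = ncfg or NucleoidConfig()
    filt = tophat_rgb(img, mcfg)
    gray = gray_of_rgb(filt)
    mask = extended_maxima(gray, ncfg.h, ncfg.connectivity)
    mask = clean_mask(mask, 0, remove_edge=True)
    records = measure_regions(mask, gray)
    kept, discarded = filter_regions(
        records, ncfg.min_area_px, ncfg.max_area_px, ncfg.max_perimeter_px
    )
    logger.info(
        "nucleoid segmentation: %d maxima components, %d kept, %d discarded",
        len(records), len(kept), len(discarded),
    )
    labels, _ = ndi.label(mask.pixels, structure=_conn_structure(mask.connectivity))
    out = []
    for rec in kept:
        single = BinaryMask(labels == rec.label, mask.connectivity)
        circ, ecc = shape_descriptors(rec, single)
        out.append(NucleoidRecord(rec, circ, ecc, excluded=False))
    return out


def apply_exclusions(
    records: list[NucleoidRecord], exclusion_ids: list[int]
) -> list[NucleoidRecord]:
    """Flag records whose label appears in the exclusion list.

    Unknown ids produce a warning, not an error.  Downstream statistics use
    only records with ``excluded=False``.
    """
    known = {rec.region.label for rec in records}
    unknown = [i for i in exclusion_ids if i not in known]
    if unknown:
        warnings.warn(f"exclusion ids not present in records: {unknown}", stacklevel=2)
    excl = set(exclusion_ids)
    return [
        NucleoidRecord(r.region, r.circularity, r.eccentricity, r.region.label in excl)
        for r in records
    ]


def read_exclusion_file(path) -> list[int]:
    """Read one integer label per line; '#' comments and blanks allowed."""
    ids = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            try:
                ids.append(int(line))
            except ValueError as exc:
                raise ContractError(
                    f"{path}:{lineno}: not an integer label: {line!r}"
                ) from exc
    return ids


def to_frame(records: list[NucleoidRecord], image_id: str = "") -> pd.DataFrame:
    rows = [
        {
            "image_id": image_id,
            "nucleoid_id": r.region.label,
            "centroid_row": r.region.centroid[0],
            "centroid_col": r.region.centroid[1],
            "area_px": r.region.area_px,
            "perimeter_px": r.region.perimeter_px,
            "circularity": r.circularity,
            "eccentricity": r.eccentricity,
            "excluded": r.excluded,
        }
        for r in sorted(records, key=lambda r: r.region.label)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "image_id",
            "nucleoid_id",
            "centroid_row",
            "centroid_col",
            "area_px",
            "perimeter_px",
            "circularity",
            "eccentricity",
            "excluded",
        ],
    )
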