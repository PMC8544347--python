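"""Seeded generator of synthetic micrographs with ground truth.

Every pipeline in this package is validated against scenes rendered by this
module: rod-shaped (spherocylinder) cells at the camera geometry of the
real instrument (2560 x 1920 px, 52 nm/px), painted either blue-dominant
(DAPI / membrane-intact) or red-dominant (EB / membrane-damaged, with a
configurable bleed-through of the red stain into the blue channel), with
optional nucleoid foci (compact bright "condensed" discs or dim elongated
"diffuse" clouds), smooth low-frequency background, shot-like noise, and —
to exercise the cleanup filters — edge-touching cells and cell aggregates.

Cells are rendered with hard edges (no antialiasing) and painted opaquely,
so per-cell area and mean-intensity identities are exact by construction;
an optional Gaussian blur flag trades this exactness for realism.

A paired AFM height map can be generated whose cell positions are related
to the fluorescence frame by a known similarity transform; intact cells
are smooth rods of ~300 nm peak height, membrane-damaged cells appear
deflated (40 % height) with globular surface debris.  The applied transform
is stored in the ground truth so registration can be tested closed-loop.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .afmreg import HeightMap, SimilarityTransform
from .errors import ContractError, PlacementError
from .imgio import MultichannelImage, write_rgb_image
from . import afmreg

logger = logging.getLogger(__name__)

CLASS_INTACT = "intact"
CLASS_DAMAGED = "damaged"


@dataclass
class SceneSpec:
    """Declarative description of one synthetic scene.

    Geometry defaults reproduce the real camera frame (2560 x 1920 px at
    52 nm/px) and typical rod-cell dimensions (0.8 um wide, 1-3 um long).
    """

    shape_px: tuple[int, int] = (1920, 2560)
    pixel_size_nm: float = 52.0
    n_intact: int = 10
    n_damaged: int = 5
    cell_length_um: tuple[float, float] = (1.0, 3.0)
    cell_width_um: float = 0.8
    intact_color: tuple[int, int, int] = (20, 40, 200)
    damaged_color: tuple[int, int, int] = (200, 30, 0)
    bleed_fraction: float = 0.2  # EB bleed-through into the blue channel
    brightness_jitter: float = 0.1  # per-cell multiplicative spread
    nucleoid_mode: str = "none"  # none | condensed | diffuse
    nucleoid_amplitude: float = 100.0
    background: tuple[float, float, float] = (10.0, 0.0, 0.0)  # offset, ramp, blobs
    noise_model: str = "gaussian"  # none | gaussian | poisson_like
    noise_sigma: float = 2.0
    n_edge_cells: int = 0
    n_aggregates: int = 0
    min_separation_px: float = 15.0
    blur_sigma: float = 0.0
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self):
        if min(self.shape_px) < 16:
            raise ContractError("scene must be at least 16 px on a side")
        if self.pixel_size_nm <= 0 or self.cell_width_um <= 0:
            raise ContractError("geometry parameters must be positive")
        if self.cell_length_um[0] > self.cell_length_um[1]:
            raise ContractError("cell_length_um range must be (lo, hi)")
        if not 0 <= self.bleed_fraction <= 0.5:
            raise ContractError("bleed_fraction must be in [0, 0.5]")
        if self.nucleoid_mode not in ("none", "condensed", "diffuse"):
            raise ContractError(f"unknown nucleoid_mode {self.nucleoid_mode!r}")
        if self.noise_model not in ("none", "gaussian", "poisson_like"):
            raise ContractError(f"unknown noise_model {self.noise_model!r}")


@dataclass
class CellTruth:
    cell_id: int
    cell_class: str
    centroid: tuple[float, float]
    painted_rgb: tuple[int, int, int]
    area_px: int
    length_px: float
    width_px: float
    theta_rad: float
    touches_edge: bool = False
    aggregate: bool = False
    nucleoid_present: bool = False
    nucleoid_centroid: tuple[float, float] | None = None
    nucleoid_area_px: int = 0
    deflated: bool = False
    afm_centroid: tuple[float, float] | None = None


@dataclass
class GroundTruth:
    cells: list[CellTruth]
    seed: int
    spec: SceneSpec
    tform: SimilarityTransform | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            rows.append(
                {
                    "cell_id": c.cell_id,
                    "cell_class": c.cell_class,
                    "centroid_row": c.centroid[0],
                    "centroid_col": c.centroid[1],
                    "painted_r": c.painted_rgb[0],
                    "painted_g": c.painted_rgb[1],
                    "painted_b": c.painted_rgb[2],
                    "area_px": c.area_px,
                    "length_px": c.length_px,
                    "width_px": c.width_px,
                    "theta_rad": c.theta_rad,
                    "touches_edge": c.touches_edge,
                    "aggregate": c.aggregate,
                    "nucleoid_present": c.nucleoid_present,
                    "nucleoid_row": (c.nucleoid_centroid or (np.nan, np.nan))[0],
                    "nucleoid_col": (c.nucleoid_centroid or (np.nan, np.nan))[1],
                    "nucleoid_area_px": c.nucleoid_area_px,
                    "deflated": c.deflated,
                    "afm_row": (c.afm_centroid or (np.nan, np.nan))[0],
                    "afm_col": (c.afm_centroid or (np.nan, np.nan))[1],
                }
            )
        return pd.DataFrame(rows)

    def well_separated(self) -> list[CellTruth]:
        """Cells that the pipelines are expected to recover: in the frame
        interior and not part of an aggregate."""
        return [c for c in self.cells if not c.touches_edge and not c.aggregate]


# ---------------------------------------------------------------------------
# geometry helpers


def _rod_geometry(spec: SceneSpec, rng: np.random.Generator) -> tuple[float, float, float]:
    """(length_px, width_px, theta) of one random cell."""
    scale = 1000.0 / spec.pixel_size_nm
    length = rng.uniform(*spec.cell_length_um) * scale
    width = spec.cell_width_um * scale
    theta = rng.uniform(0.0, np.pi)
    return length, width, theta


def _rod_patch(
    shape: tuple[int, int],
    centroid: tuple[float, float],
    theta: float,
    length: float,
    width: float,
    radius_extra: float = 0.0,
):
    """Rasterize a spherocylinder on its bounding patch.

    Returns ``(r0, c0, mask, dist, u)`` where ``mask`` marks pixels within
    ``width/2 + radius_extra`` of the medial segment, ``dist`` is the
    distance of each patch pixel to the segment and ``u`` its signed
    coordinate along the cell axis.
    """
    r = width / 2.0 + radius_extra
    half = max(0.0, length / 2.0 - width / 2.0)
    a = np.array([np.cos(theta), np.sin(theta)])
    c = np.asarray(centroid, dtype=float)
    p1, p2 = c - half * a, c + half * a
    lo = np.floor(np.minimum(p1, p2) - r - 1).astype(int)
    hi = np.ceil(np.maximum(p1, p2) + r + 2).astype(int)
    r0, c0 = np.maximum(lo, 0)
    r1, c1 = np.minimum(hi, shape)
    if r0 >= r1 or c0 >= c1:
        return r0, c0, np.zeros((0, 0), bool), np.zeros((0, 0)), np.zeros((0, 0))
    rows, cols = np.mgrid[r0:r1, c0:c1]
    vr = rows - p1[0]
    vc = cols - p1[1]
    seg = 2.0 * half
    t = np.clip(vr * a[0] + vc * a[1], 0.0, seg if seg > 0 else 0.0)
    dr = vr - t * a[0]
    dc = vc - t * a[1]
    dist = np.hypot(dr, dc)
    u = (rows - c[0]) * a[0] + (cols - c[1]) * a[1]
    return r0, c0, dist <= r, dist, u


def spherocylinder_area_px(length_px: float, width_px: float) -> float:
    """Analytic area of the continuous spherocylinder footprint."""
    r = width_px / 2.0
    return (length_px - width_px) * width_px + np.pi * r * r


# ---------------------------------------------------------------------------
# scene generation


def _paint_cell(canvas, occupied, spec, rng, cls, cell_id, *, edge=False, aggregate=False,
                max_tries=300) -> CellTruth:
    H, W = spec.shape_px
    sep = spec.min_separation_px
    for _ in range(max_tries):
        length, width, theta = _rod_geometry(spec, rng)
        margin = length / 2.0 + 2.0
        if edge:
            side = rng.integers(4)
            if side == 0:
                cen = (rng.uniform(-width / 4, width / 4), rng.uniform(margin, W - margin))
            elif side == 1:
                cen = (H - 1 + rng.uniform(-width / 4, width / 4), rng.uniform(margin, W - margin))
            elif side == 2:
                cen = (rng.uniform(margin, H - margin), rng.uniform(-width / 4, width / 4))
            else:
                cen = (rng.uniform(margin, H - margin), W - 1 + rng.uniform(-width / 4, width / 4))
        else:
            if 2 * margin >= min(H, W):
                continue
            cen = (rng.uniform(margin, H - margin), rng.uniform(margin, W - margin))
        r0, c0, grown, _, _ = _rod_patch((H, W), cen, theta, length, width, radius_extra=sep)
        if grown.size == 0:
            continue
        if not aggregate and occupied[r0 : r0 + grown.shape[0], c0 : c0 + grown.shape[1]][grown].any():
            continue
        r0, c0, mask, dist, u = _rod_patch((H, W), cen, theta, length, width)
        if mask.sum() == 0:
            continue
        if edge:
            rows = np.argwhere(mask) + (r0, c0)
            if not (
                (rows[:, 0] == 0).any() or (rows[:, 0] == H - 1).any()
                or (rows[:, 1] == 0).any() or (rows[:, 1] == W - 1).any()
            ):
                continue

        base = np.array(spec.intact_color if cls == CLASS_INTACT else spec.damaged_color, float)
        if cls == CLASS_DAMAGED:
            base[2] = max(base[2], spec.bleed_fraction * base[0])
        factor = 1.0 + spec.brightness_jitter * rng.uniform(-1.0, 1.0)
        painted = np.clip(np.rint(base * factor), 0, 2**spec.bit_depth - 1).astype(int)

        view = canvas[r0 : r0 + mask.shape[0], c0 : c0 + mask.shape[1]]
        view[mask] = painted
        occupied[r0 : r0 + mask.shape[0], c0 : c0 + mask.shape[1]] |= mask

        nuc_present, nuc_cen, nuc_area = False, None, 0
        if spec.nucleoid_mode != "none":
            A = spec.nucleoid_amplitude
            if spec.nucleoid_mode == "condensed":
                # compact bright spot at the cell centre (flat-top profile)
                rc = np.hypot(u, dist)
                profile = A * np.exp(-((rc / 7.0) ** 4))
            else:
                # dim cloud elongated along the cell axis; dist ~ |v| within
                # the rod body
                q = (u / 16.0) ** 2 + (dist / 5.0) ** 2
                profile = (A / 2.0) * np.exp(-(q**2))
            profile = np.where(mask, profile, 0.0)
            view += profile[:, :, None]
            core = profile >= profile.max() / 2.0
            if core.any():
                nuc_present = True
                pts = np.argwhere(core)
                nuc_cen = (float(pts[:, 0].mean() + r0), float(pts[:, 1].mean() + c0))
                nuc_area = int(core.sum())

        pts = np.argwhere(mask)
        centroid = (float(pts[:, 0].mean() + r0), float(pts[:, 1].mean() + c0))
        return CellTruth(
            cell_id=cell_id,
            cell_class=cls,
            centroid=centroid,
            painted_rgb=tuple(int(v) for v in painted),
            area_px=int(mask.sum()),
            length_px=length,
            width_px=width,
            theta_rad=theta,
            touches_edge=edge,
            aggregate=aggregate,
            nucleoid_present=nuc_present,
            nucleoid_centroid=nuc_cen,
            nucleoid_area_px=nuc_area,
        )
    raise PlacementError(
        f"could not place cell {cell_id} after {max_tries} tries", achieved=cell_id - 1
    )


def generate_scene(spec: SceneSpec) -> tuple[MultichannelImage, GroundTruth]:
    """Render one scene; identical specs give bit-identical output."""
    rng = np.random.default_rng(spec.seed)
    H, W = spec.shape_px
    offset, ramp_amp, blob_amp = spec.background
    canvas = np.full((H, W, 3), float(offset))
    if ramp_amp:
        ramp = ramp_amp * np.linspace(0.0, 1.0, W)[None, :]
        canvas += ramp[:, :, None]
    if blob_amp:
        blobs = np.zeros((H, W))
        for _ in range(3):
            cy, cx = rng.uniform(0, H), rng.uniform(0, W)
            sig = rng.uniform(min(H, W) / 8, min(H, W) / 4)
            yy, xx = np.mgrid[0:H, 0:W]
            blobs += np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig**2)))
        blobs *= blob_amp / max(blobs.max(), 1e-9)
        canvas += blobs[:, :, None]

    occupied = np.zeros((H, W), dtype=bool)
    cells: list[CellTruth] = []
    cid = 1
    plan = [CLASS_INTACT] * spec.n_intact + [CLASS_DAMAGED] * spec.n_damaged
    for cls in plan:
        cells.append(_paint_cell(canvas, occupied, spec, rng, cls, cid))
        cid += 1
    for _ in range(spec.n_edge_cells):
        cls = CLASS_INTACT if rng.uniform() < 0.5 else CLASS_DAMAGED
        cells.append(_paint_cell(canvas, occupied, spec, rng, cls, cid, edge=True))
        cid += 1
    for _ in range(spec.n_aggregates):
        cls = CLASS_INTACT if rng.uniform() < 0.5 else CLASS_DAMAGED
        anchor = _paint_cell(canvas, occupied, spec, rng, cls, cid, aggregate=False)
        anchor.aggregate = True
        cells.append(anchor)
        cid += 1
        for _ in range(2):  # overlap two more rods onto the anchor
            length, width, theta = _rod_geometry(spec, rng)
            jitter = rng.uniform(-width / 2, width / 2, size=2)
            cen = (anchor.centroid[0] + jitter[0], anchor.centroid[1] + jitter[1])
            r0, c0, mask, _, _ = _rod_patch((H, W), cen, theta, length, width)
            if mask.size == 0:
                continue
            base = np.array(spec.intact_color if cls == CLASS_INTACT else spec.damaged_color, float)
            if cls == CLASS_DAMAGED:
                base[2] = max(base[2], spec.bleed_fraction * base[0])
            view = canvas[r0 : r0 + mask.shape[0], c0 : c0 + mask.shape[1]]
            view[mask] = np.rint(base)
            occupied[r0 : r0 + mask.shape[0], c0 : c0 + mask.shape[1]] |= mask
            pts = np.argwhere(mask)
            cells.append(
                CellTruth(
                    cell_id=cid,
                    cell_class=cls,
                    centroid=(float(pts[:, 0].mean() + r0), float(pts[:, 1].mean() + c0)),
                    painted_rgb=tuple(int(v) for v in np.rint(base)),
                    area_px=int(mask.sum()),
                    length_px=length,
                    width_px=width,
                    theta_rad=theta,
                    aggregate=True,
                )
            )
            cid += 1

    if spec.blur_sigma > 0:
        for c in range(3):
            canvas[:, :, c] = ndi.gaussian_filter(canvas[:, :, c], spec.blur_sigma)
    if spec.noise_model == "gaussian":
        canvas = canvas + rng.normal(0.0, spec.noise_sigma, canvas.shape)
    elif spec.noise_model == "poisson_like":
        canvas = rng.poisson(np.maximum(canvas, 0.0)).astype(float)

    lim = 2**spec.bit_depth - 1
    pixels = np.clip(np.rint(canvas), 0, lim).astype(np.uint8 if spec.bit_depth == 8 else np.uint16)
    img = MultichannelImage(
        pixels, spec.bit_depth, spec.pixel_size_nm, image_id=f"synthetic_seed{spec.seed}"
    )
    return img, GroundTruth(cells=cells, seed=spec.seed, spec=spec)


# ---------------------------------------------------------------------------
# paired AFM scene


def generate_afm_pair(
    spec: SceneSpec,
    tform: SimilarityTransform,
    deflated_fraction: float = 0.0,
) -> tuple[HeightMap, MultichannelImage, GroundTruth]:
    """Fluorescence scene plus an AFM height map related by ``tform``.

    ``tform`` maps fluorescence pixels to AFM pixels; cell positions in the
    height map are the transformed fluorescence positions, so estimating the
    transform from matched centroids must recover ``tform``.  A
    ``deflated_fraction`` of the cells (membrane-damaged ones first) is
    rendered deflated: 40 % of the 300 nm intact peak height with seeded
    globular debris on top.
    """
    if not 0.0 <= deflated_fraction <= 1.0:
        raise ContractError("deflated_fraction must be in [0, 1]")
    img, truth = generate_scene(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xAF]))

    corners = np.array(
        [[0, 0], [0, spec.shape_px[1] - 1], [spec.shape_px[0] - 1, 0],
         [spec.shape_px[0] - 1, spec.shape_px[1] - 1]], dtype=float
    )
    mapped = tform.apply(corners)
    shape_afm = tuple(int(np.ceil(mapped[:, i].max())) + 1 for i in (0, 1))
    heights = np.zeros(shape_afm)

    n_deflated = int(round(deflated_fraction * len(truth.cells)))
    order = sorted(truth.cells, key=lambda c: (c.cell_class != CLASS_DAMAGED, c.cell_id))
    deflated_ids = {c.cell_id for c in order[:n_deflated]}

    peak_intact = 300.0
    for cell in truth.cells:
        cen_afm = tuple(tform.apply(np.array([cell.centroid]))[0])
        cell.afm_centroid = (float(cen_afm[0]), float(cen_afm[1]))
        cell.deflated = cell.cell_id in deflated_ids
        # direction of the cell axis after the transform
        axis = np.array([np.cos(cell.theta_rad), np.sin(cell.theta_rad)])
        p2 = tform.apply(np.array([np.asarray(cell.centroid) + axis]))[0]
        d = p2 - np.asarray(cen_afm)
        theta_afm = float(np.arctan2(d[1], d[0]))
        length = cell.length_px * tform.scale
        width = cell.width_px * tform.scale
        r0, c0, mask, dist, _ = _rod_patch(shape_afm, cen_afm, theta_afm, length, width)
        if mask.size == 0 or not mask.any():
            continue
        r = width / 2.0
        peak = peak_intact * (0.4 if cell.deflated else 1.0)
        prof = peak * np.sqrt(np.maximum(0.0, 1.0 - (dist / r) ** 2))
        if cell.deflated:
            n_bumps = int(rng.integers(4, 9))
            pts = np.argwhere(mask)
            yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
            for _ in range(n_bumps):
                by, bx = pts[rng.integers(len(pts))]
                amp = 60.0 * rng.uniform(0.5, 1.5)
                sig = rng.uniform(1.5, 3.0)
                prof += amp * np.exp(-(((yy - by) ** 2 + (xx - bx) ** 2) / (2 * sig**2)))
        prof = np.where(mask, prof, 0.0)
        view = heights[r0 : r0 + mask.shape[0], c0 : c0 + mask.shape[1]]
        np.maximum(view, prof, out=view)

    px_afm_nm = spec.pixel_size_nm / tform.scale
    scan = (shape_afm[1] * px_afm_nm / 1000.0, shape_afm[0] * px_afm_nm / 1000.0)
    truth.tform = tform
    return HeightMap(heights, scan), img, truth


# ---------------------------------------------------------------------------
# fixtures on disk


def _spec_dict(spec: SceneSpec) -> dict:
    d = dataclasses.asdict(spec)
    return d


def write_fixture(
    out_dir,
    img: MultichannelImage,
    truth: GroundTruth,
    heights: HeightMap | None = None,
) -> dict[str, Path]:
    """Write a self-describing fixture: TIFF scene, CSV truth, JSON spec echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out / "scene.tif",
        "truth": out / "truth.csv",
        "spec": out / "spec.json",
    }
    write_rgb_image(img, paths["image"])
    truth.to_frame().to_csv(paths["truth"], index=False)
    payload = {"seed": truth.seed, "spec": _spec_dict(truth.spec)}
    if truth.tform is not None:
        payload["tform"] = {
            "scale": truth.tform.scale,
            "rotation_rad": truth.tform.rotation_rad,
            "d_row": truth.tform.translation[0],
            "d_col": truth.tform.translation[1],
        }
    with open(paths["spec"], "w") as fh:
        json.dump(payload, fh, indent=2)
    if heights is not None:
        if heights.heights.size > 512 * 512:  # text format impractical at scale
            paths["heights"] = out / "heights.tif"
            afmreg.write_height_map_tiff(heights, paths["heights"])
        else:
            paths["heights"] = out / "heights.txt"
            afmreg.write_height_map(heights, paths["heights"])
    return paths


# ---------------------------------------------------------------------------
# presets


def preset_spec(name: str, small: bool = False, seed: int = 0, **overrides) -> SceneSpec:
    """Named scene presets for the CLI (``--small`` is 640 x 480)."""
    shape = (480, 640) if small else (1920, 2560)
    base: dict = {"shape_px": shape, "seed": seed}
    # each preset draws cell lengths whose footprint falls inside the
    # corresponding pipeline's area window at 52 nm/px
    if name == "tht":
        base.update(
            n_intact=12 if small else 40,
            n_damaged=0,
            intact_color=(0, 180, 0),
            nucleoid_mode="none",
            cell_length_um=(1.3, 3.0),  # area within [300, 1000] px
        )
    elif name == "membrane":
        base.update(
            n_intact=10 if small else 30,
            n_damaged=5 if small else 15,
            cell_length_um=(1.6, 2.9),  # area within [400, 2000] px
        )
    elif name == "nucleoid":
        base.update(
            n_intact=8 if small else 25,
            n_damaged=4 if small else 12,
            nucleoid_mode="condensed",
            cell_length_um=(1.6, 2.9),
        )
    elif name == "afm":
        base.update(
            n_intact=6 if small else 12,
            n_damaged=4 if small else 8,
            cell_length_um=(1.6, 2.9),
        )
    else:
        raise ContractError(f"unknown preset {name!r}")
    base.update(overrides)
    return SceneSpec(**base)
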