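"""AFM / fluorescence image registration.

An AFM height map and a fluorescence micrograph of the same field are
related by an isotropic similarity transform (scale + rotation +
translation — dried cells must not shear, so affine terms are deliberately
unsupported).  The transform maps fluorescence pixel coordinates to AFM
pixel coordinates and is estimated from control-point pairs by least
squares (Umeyama), replacing interactive registration tools with a
reproducible artifact.  The fluorescence image is then warped into the AFM
frame and displayed side-by-side or draped over the shaded topography.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from skimage import transform as sktransform

from .errors import ContractError, FormatError
from .imgio import MultichannelImage, _dtype_for_depth

logger = logging.getLogger(__name__)

_CONVENTION = "fluorescence (row,col) -> AFM (row,col); xy = (col,row)"


@dataclass
class HeightMap:
    """AFM topography: heights in nm on a regular grid, row 0 at top."""

    heights: np.ndarray
    scan_size_um: tuple[float, float]  # (width, height) in um

    def __post_init__(self):
        h = np.asarray(self.heights, dtype=np.float64)
        if h.ndim != 2:
            raise ContractError(f"height map must be 2-D, got {h.shape}")
        if not np.isfinite(h).all():
            raise ContractError("height map contains non-finite values")
        if self.scan_size_um[0] <= 0 or self.scan_size_um[1] <= 0:
            raise ContractError("scan size must be positive")
        self.heights = h

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape


@dataclass
class SimilarityTransform:
    """Isotropic scale + rotation + translation, fluorescence -> AFM pixels.

    ``rotation_rad`` follows the scikit-image convention (positive rotates
    the +x/column axis toward +y/row, i.e. clockwise on screen);
    ``translation`` is (d_row, d_col).
    """

    scale: float = 1.0
    rotation_rad: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.scale <= 0:
            raise ContractError("scale must be > 0")

    def _sk(self) -> sktransform.SimilarityTransform:
        return sktransform.SimilarityTransform(
            scale=self.scale,
            rotation=self.rotation_rad,
            translation=(self.translation[1], self.translation[0]),
        )

    def apply(self, points_rowcol: np.ndarray) -> np.ndarray:
        """Map (n, 2) row/col points from fluorescence to AFM frame."""
        pts = np.asarray(points_rowcol, dtype=np.float64)
        xy = pts[:, ::-1]
        out = self._sk()(xy)
        return out[:, ::-1]

    def inverse(self) -> "SimilarityTransform":
        inv = self._sk().inverse
        return _from_sk(inv)

    def to_json(self, path) -> None:
        payload = {
            "scale": self.scale,
            "rotation_rad": self.rotation_rad,
            "d_row": self.translation[0],
            "d_col": self.translation[1],
            "convention": _CONVENTION,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimilarityTransform":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            scale=payload["scale"],
            rotation_rad=payload["rotation_rad"],
            translation=(payload["d_row"], payload["d_col"]),
        )


def _from_sk(sk: sktransform.SimilarityTransform) -> SimilarityTransform:
    tx, ty = sk.translation
    return SimilarityTransform(
        scale=float(sk.scale),
        rotation_rad=float(sk.rotation),
        translation=(float(ty), float(tx)),
    )


@dataclass
class ControlPoints:
    """Paired (row, col) landmarks in the fluorescence and AFM frames."""

    fluor: np.ndarray  # (n, 2) row/col
    afm: np.ndarray  # (n, 2) row/col

    def __post_init__(self):
        f = np.asarray(self.fluor, dtype=np.float64)
        a = np.asarray(self.afm, dtype=np.float64)
        if f.ndim != 2 or f.shape[1] != 2 or a.shape != f.shape:
            raise ContractError("control points must be matching (n, 2) arrays")
        if f.shape[0] < 2:
            raise ContractError("need at least 2 control-point pairs")
        if len(np.unique(f, axis=0)) != len(f):
            raise ContractError("duplicated source (fluorescence) control points")
        self.fluor, self.afm = f, a

    @classmethod
    def read_csv(cls, path) -> "ControlPoints":
        frame = pd.read_csv(path)
        required = ["fluor_row", "fluor_col", "afm_row", "afm_col"]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise FormatError(f"{path}: missing control-point columns {missing}")
        return cls(
            frame[["fluor_row", "fluor_col"]].to_numpy(),
            frame[["afm_row", "afm_col"]].to_numpy(),
        )

    def write_csv(self, path) -> None:
        pd.DataFrame(
            {
                "fluor_row": self.fluor[:, 0],
                "fluor_col": self.fluor[:, 1],
                "afm_row": self.afm[:, 0],
                "afm_col": self.afm[:, 1],
            }
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# height-map I/O


def read_height_map(path) -> HeightMap:
    """Read a height map from plain text or single-channel TIFF.

    The text format is rows of whitespace-separated heights in nm, with
    '#'-prefixed header lines; keys ``scan_size_um_x`` / ``scan_size_um_y``
    give the physical scan size and are required (for TIFF they are read
    from an embedded JSON description).
    """
    path_s = str(path)
    if path_s.lower().endswith((".tif", ".tiff")):
        with tifffile.TiffFile(path_s) as tf:
            arr = tf.asarray()
            desc = tf.pages[0].description
        meta = {}
        if desc:
            try:
                meta = json.loads(desc)
            except ValueError:
                pass
        if "scan_size_um_x" not in meta or "scan_size_um_y" not in meta:
            raise FormatError(f"{path}: TIFF height map lacks scan-size metadata")
        if arr.ndim != 2:
            raise FormatError(f"{path}: height map TIFF must be single-channel")
        return HeightMap(arr.astype(np.float64), (float(meta["scan_size_um_x"]), float(meta["scan_size_um_y"])))

    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    try:
                        header[key.strip()] = float(val)
                    except ValueError:
                        pass
                continue
            try:
                rows.append([float(tok) for tok in line.split()])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric token") from exc
            if len(rows) > 1 and len(rows[-1]) != len(rows[0]):
                raise FormatError(
                    f"{path}: ragged row {lineno}: {len(rows[-1])} values, expected {len(rows[0])}"
                )
    if not rows:
        raise FormatError(f"{path}: no data rows")
    if "scan_size_um_x" not in header or "scan_size_um_y" not in header:
        raise FormatError(f"{path}: missing scan_size_um_x/scan_size_um_y header")
    return HeightMap(np.array(rows), (header["scan_size_um_x"], header["scan_size_um_y"]))


def write_height_map_tiff(hm: HeightMap, path) -> None:
    """Write a height map as float TIFF with scan-size metadata."""
    desc = json.dumps(
        {"scan_size_um_x": hm.scan_size_um[0], "scan_size_um_y": hm.scan_size_um[1]}
    )
    tifffile.imwrite(path, hm.heights.astype(np.float32), description=desc)


def write_height_map(hm: HeightMap, path) -> None:
    """Write the plain-text height-map format read by :func:`read_height_map`."""
    with open(path, "w") as fh:
        fh.write(f"# scan_size_um_x = {float(hm.scan_size_um[0]):.17g}\n")
        fh.write(f"# scan_size_um_y = {float(hm.scan_size_um[1]):.17g}\n")
        for row in hm.heights:
            fh.write(" ".join(f"{float(v):.17g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# estimation, warping, export


def estimate_similarity(points: ControlPoints) -> tuple[SimilarityTransform, float]:
    """Least-squares (Umeyama) similarity fit of the control points.

    Returns the transform and the RMS of the target-point residuals in px.
    """
    src = points.fluor[:, ::-1]  # to xy
    dst = points.afm[:, ::-1]
    if np.allclose(src, src[0]):
        raise ContractError("all source control points coincide; geometry degenerate")
    sk = sktransform.estimate_transform("similarity", src, dst)
    if not np.isfinite(sk.params).all():
        raise ContractError("similarity estimation failed (degenerate geometry)")
    resid = sk(src) - dst
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return _from_sk(sk), rms


def warp_fluorescence(
    img: MultichannelImage,
    tform: SimilarityTransform,
    out_shape: tuple[int, int],
) -> MultichannelImage:
    """Resample the fluorescence image into the AFM frame.

    Inverse-mapped bilinear interpolation; pixels falling outside the
    source domain are 0.  All channels are warped identically and the bit
    depth is preserved.
    """
    sk = tform._sk()
    out = np.empty((*out_shape, 3), dtype=np.float64)
    for c in range(3):
        out[:, :, c] = sktransform.warp(
            img.pixels[:, :, c].astype(np.float64),
            inverse_map=sk.inverse,
            output_shape=out_shape,
            order=1,
            cval=0.0,
            preserve_range=True,
        )
    lim = 2**img.bit_depth - 1
    out = np.clip(np.rint(out), 0, lim).astype(_dtype_for_depth(img.bit_depth))
    return MultichannelImage(out, img.bit_depth, img.pixel_size_nm / tform.scale, img.image_id + "_warped")


def crop_to_scan(
    img: MultichannelImage, afm: HeightMap, tform: SimilarityTransform
) -> MultichannelImage:
    """Crop the fluorescence image to the AFM field of view.

    The AFM scan corners are mapped back into fluorescence coordinates;
    the axis-aligned bounding box of the mapped corners, clipped to the
    image, is returned.  An empty intersection is an error.
    """
    h, w = afm.shape
    corners = np.array([[0, 0], [0, w - 1], [h - 1, 0], [h - 1, w - 1]], dtype=float)
    back = tform.inverse().apply(corners)
    rmin, cmin = np.floor(back.min(axis=0)).astype(int)
    rmax, cmax = np.ceil(back.max(axis=0)).astype(int) + 1
    H, W = img.shape
    r0, c0 = max(0, rmin), max(0, cmin)
    r1, c1 = min(H, rmax), min(W, cmax)
    if r0 >= r1 or c0 >= c1:
        raise ContractError("AFM footprint does not intersect the fluorescence image")
    if (r0, c0) != (max(0, rmin), max(0, cmin)) or rmin < 0 or cmin < 0 or rmax > H or cmax > W:
        logger.info("AFM footprint straddles the image border; crop clipped to bounds")
    return MultichannelImage(
        img.pixels[r0:r1, c0:c1].copy(),
        img.bit_depth,
        img.pixel_size_nm,
        img.image_id + "_crop",
    )


def _relief_shade(heights: np.ndarray) -> np.ndarray:
    """Lambertian shading of the topography, 1.0 on flat terrain.

    Heights (nm) and the pixel grid have incommensurate units, so the relief
    is normalized before shading: the full height range maps to 5 px of
    vertical relief, keeping the rendering scale-invariant.
    """
    span = float(heights.max() - heights.min())
    scaled = heights * (5.0 / span) if span > 0 else heights
    gy, gx = np.gradient(scaled)
    # light direction (in gradient units): oblique from the upper left
    lx, ly, lz = -1.0, -1.0, 4.0
    norm_l = math.sqrt(lx * lx + ly * ly + lz * lz)
    nz = 1.0 / np.sqrt(gx**2 + gy**2 + 1.0)
    shade = (-gx * lx - gy * ly + lz) * nz / norm_l
    shade /= lz / norm_l  # flat surface -> exactly 1
    return np.clip(shade, 0.0, 1.0)


def export_overlay(
    afm: HeightMap,
    warped: MultichannelImage,
    mode: str,
    path=None,
) -> MultichannelImage:
    """Compose the registered AFM/fluorescence product and optionally save it.

    ``side_by_side`` puts a min-max grayscale rendering of the heights next
    to the warped fluorescence (both panels share the fluorescence panel's
    pixel dimensions).  ``draped`` multiplies the fluorescence colors by a
    shaded-relief rendering of the topography (flat topography reproduces
    the color image exactly); it requires matching shapes.
    """
    lim = 2**warped.bit_depth - 1
    hmin, hmax = float(afm.heights.min()), float(afm.heights.max())
    logger.info("height-to-gray mapping: min %.3f nm -> 0, max %.3f nm -> %d", hmin, hmax, lim)
    if mode == "side_by_side":
        span = hmax - hmin
        norm = (afm.heights - hmin) / span if span > 0 else np.zeros(afm.shape)
        if afm.shape != warped.shape:
            norm = sktransform.resize(norm, warped.shape, order=1, anti_aliasing=True)
        panel = np.rint(norm * lim).astype(warped.pixels.dtype)
        panel_rgb = np.stack([panel] * 3, axis=-1)
        composed = np.concatenate([panel_rgb, warped.pixels], axis=1)
    elif mode == "draped":
        if afm.shape != warped.shape:
            raise ContractError(
                f"draped mode needs matching shapes, got {afm.shape} vs {warped.shape}"
            )
        shade = _relief_shade(afm.heights)
        composed = np.rint(warped.pixels.astype(np.float64) * shade[:, :, None])
        composed = np.clip(composed, 0, lim).astype(warped.pixels.dtype)
    else:
        raise ContractError(f"unknown overlay mode {mode!r}")
    out = MultichannelImage(composed, warped.bit_depth, warped.pixel_size_nm, warped.image_id + "_" + mode)
    if path is not None:
        iio.imwrite(path, out.pixels)
    return out


# ---------------------------------------------------------------------------
# optional automatic registration (best effort)


def auto_register(
    fluor_gray: np.ndarray,
    afm: HeightMap,
    scales: np.ndarray | None = None,
    rotations_deg: np.ndarray | None = None,
) -> tuple[SimilarityTransform, float]:
    """Coarse grid search over rotation and scale with NCC on gradient
    magnitudes, refined by local optimization.  Best effort; always returns
    its normalized-correlation score alongside the transform."""
    from scipy import optimize

    f = np.asarray(fluor_gray, dtype=np.float64)
    g = afm.heights

    def grad_mag(a):
        gy, gx = np.gradient(a)
        m = np.hypot(gx, gy)
        s = m.std()
        return (m - m.mean()) / s if s > 0 else m * 0

    gm_afm = grad_mag(g)

    def score(params):
        s, rot, dr, dc = params
        if s <= 0.05:
            return 1.0
        t = SimilarityTransform(s, rot, (dr, dc))
        warped = sktransform.warp(
            f, inverse_map=t._sk().inverse, output_shape=afm.shape, order=1, cval=0.0,
            preserve_range=True,
        )
        gm_w = grad_mag(warped)
        return -float(np.mean(gm_w * gm_afm))

    scales = scales if scales is not None else np.linspace(0.5, 2.0, 7)
    rotations = (
        np.deg2rad(rotations_deg) if rotations_deg is not None else np.deg2rad(np.arange(-180, 180, 30))
    )
    best, best_s = None, 1.0
    ctr_f = np.array(f.shape, dtype=float) / 2
    ctr_a = np.array(afm.shape, dtype=float) / 2
    for s in scales:
        for rot in rotations:
            t0 = SimilarityTransform(s, rot, (0.0, 0.0))
            mapped = t0.apply(ctr_f[None, :])[0]
            dr, dc = ctr_a - mapped
            val = score((s, rot, dr, dc))
            if val < best_s:
                best_s, best = val, (s, rot, dr, dc)
    if best is None:
        raise ContractError("automatic registration found no overlap")
    res = optimize.minimize(score, best, method="Nelder-Mead", options={"maxiter": 200, "xatol": 1e-3, "fatol": 1e-6})
    s, rot, dr, dc = res.x
    return SimilarityTransform(float(s), float(rot), (float(dr), float(dc))), -float(res.fun)
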