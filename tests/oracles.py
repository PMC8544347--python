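"""Brute-force reference implementations used to validate the primitives.

These deliberately favour clarity over speed (explicit loops, iterative
fixpoints) and never share code with the package's own kernels.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi


def otsu_oracle(vals: np.ndarray, n_bins: int = 256) -> float:
    """Exhaustive search over every candidate bin edge.

    Pixels are grouped into ``n_bins`` equal bins over [min, max]; for each
    split the between-class variance is computed directly from the raw pixel
    values of the two groups; the lowest argmax edge wins.
    """
    vals = np.asarray(vals, dtype=np.float64).ravel()
    mn, mx = vals.min(), vals.max()
    if mn == mx:
        return float(mn)
    edges = np.linspace(mn, mx, n_bins + 1)
    # same binning convention as np.histogram: [e_i, e_{i+1}), last closed
    idx = np.clip(np.searchsorted(edges, vals, side="right") - 1, 0, n_bins - 1)
    best_var, best_k = -np.inf, None
    for k in range(n_bins - 1):
        lower = vals[idx <= k]
        upper = vals[idx > k]
        if len(lower) == 0 or len(upper) == 0:
            continue
        w0, w1 = len(lower), len(upper)
        var_b = w0 * w1 * (lower.mean() - upper.mean()) ** 2
        if var_b > best_var:
            best_var, best_k = var_b, k
    return float(edges[best_k + 1])


def _struct(connectivity: int) -> np.ndarray:
    return ndi.generate_binary_structure(2, 2 if connectivity == 8 else 1)


def regional_maxima_oracle(g: np.ndarray, connectivity: int) -> np.ndarray:
    """Plateau-by-plateau regional-maxima check."""
    struct = _struct(connectivity)
    out = np.zeros(g.shape, dtype=bool)
    for val in np.unique(g):
        mask = g == val
        lab, n = ndi.label(mask, structure=struct)
        for i in range(1, n + 1):
            comp = lab == i
            nb = ndi.binary_dilation(comp, structure=struct) & ~comp
            if not nb.any() or (g[nb] < val).all():
                out |= comp
    return out


def extended_maxima_oracle(f: np.ndarray, h: float, connectivity: int) -> np.ndarray:
    """Iterative grayscale reconstruction of f-h under f, then regional maxima."""
    struct = _struct(connectivity)
    f = np.asarray(f, dtype=np.float64)
    g = f - h
    while True:
        g2 = np.minimum(ndi.grey_dilation(g, footprint=struct), f)
        if np.array_equal(g2, g):
            break
        g = g2
    return regional_maxima_oracle(g, connectivity)


def nonflat_erosion_oracle(f: np.ndarray, radius: int, height: float) -> np.ndarray:
    """Direct min over the ellipsoid SE with replicate padding."""
    f = np.asarray(f, dtype=np.float64)
    H, W = f.shape
    offs = []
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            d2 = dy * dy + dx * dx
            if d2 <= radius * radius:
                hv = height * np.sqrt(max(0.0, 1.0 - d2 / (radius * radius)))
                offs.append((dy, dx, hv))
    out = np.empty_like(f)
    for y in range(H):
        for x in range(W):
            best = np.inf
            for dy, dx, hv in offs:
                yy = min(max(y + dy, 0), H - 1)
                xx = min(max(x + dx, 0), W - 1)
                best = min(best, f[yy, xx] - hv)
            out[y, x] = best
    return out


def nonflat_dilation_oracle(f: np.ndarray, radius: int, height: float) -> np.ndarray:
    """Direct max over the ellipsoid SE with replicate padding."""
    return -nonflat_erosion_oracle(-np.asarray(f, dtype=np.float64), radius, height)


def tophat_oracle(f: np.ndarray, radius: int, height: float) -> np.ndarray:
    opening = nonflat_dilation_oracle(nonflat_erosion_oracle(f, radius, height), radius, height)
    return np.asarray(f, dtype=np.float64) - opening


def disk_offsets(radius: int) -> list[tuple[int, int]]:
    """All integer offsets within Euclidean distance ``radius``."""
    return [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]


def component_areas_oracle(mask: np.ndarray, connectivity: int) -> list[int]:
    """Flood-fill component areas (explicit stack walk)."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    areas = []
    H, W = mask.shape
    for sy in range(H):
        for sx in range(W):
            if not mask[sy, sx] or seen[sy, sx]:
                continue
            stack = [(sy, sx)]
            seen[sy, sx] = True
            area = 0
            while stack:
                y, x = stack.pop()
                area += 1
                for dy, dx in nbrs:
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < H and 0 <= xx < W and mask[yy, xx] and not seen[yy, xx]:
                        seen[yy, xx] = True
                        stack.append((yy, xx))
            areas.append(area)
    return areas
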