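"""Fast grayscale erosion/dilation with large disk-shaped structuring elements.

A non-flat "ball" structuring element (radius R, height H, profile
``h(d) = H * sqrt(1 - (d/R)^2)``) is realized as a stack of flat disks: the
radial height profile is quantized into ``n_levels`` evenly spaced heights
``v_0 = H > v_1 > ... > v_{L-1} = 0`` with matching radii
``r_l = R * sqrt(1 - (v_l/H)^2)``, and

    erosion(f)  = min_l [ disk_erosion(f, r_l) - v_l ]
    dilation(f) = max_l [ disk_dilation(f, r_l) + v_l ]

This computes an exact non-flat erosion/dilation with the *quantized* SE
whose height at offset ``o`` is the level height of the smallest level disk
containing ``o``; the quantized profile differs from the continuous one by
at most ``H / (n_levels - 1)``.  Both directions use the same quantized SE,
so the derived opening is a true morphological opening (idempotent,
anti-extensive), which keeps top-hat outputs non-negative by construction.

Flat disk erosions are decomposed into per-row-offset 1-D window minima
(half-width ``w(dy) = floor(sqrt(r^2 - dy^2))``) evaluated through a
prefix-doubling sparse table, followed by vertical shift-mins, giving
O(levels * radius) full-frame passes instead of O(radius^2) per pixel.
Borders are handled by edge replication.
"""

from __future__ import annotations

import numpy as np


def _build_tables(f: np.ndarray, max_w: int, maximum: bool) -> tuple[list[np.ndarray], int]:
    """Sparse table of left-aligned row minima (or maxima) on an edge-padded copy.

    ``tables[j][y, x]`` is the min/max of ``fp[y, x : x + 2**j]`` where ``fp``
    is ``f`` padded horizontally by ``max_w`` replicated edge columns plus an
    inert tail (+/- inf) so lookups never wrap.
    """
    h, w = f.shape
    m = 2 * max_w + 1
    jmax = max(0, int(np.ceil(np.log2(m))))
    tail = 1 << jmax
    fill = -np.inf if maximum else np.inf
    fp = np.full((h, w + 2 * max_w + tail), fill, dtype=f.dtype)
    fp[:, max_w : max_w + w] = f
    if max_w:
        fp[:, :max_w] = f[:, :1]
        fp[:, max_w + w : 2 * max_w + w] = f[:, -1:]
    op = np.maximum if maximum else np.minimum
    tables = [fp]
    for j in range(1, jmax + 1):
        s = 1 << (j - 1)
        prev = tables[-1]
        cur = np.full_like(prev, fill)
        np.copyto(cur[:, :-s], op(prev[:, :-s], prev[:, s:]))
        tables.append(cur)
    return tables, max_w


def _row_window(tables: list[np.ndarray], pad: int, width: int, w: int, maximum: bool):
    """Centered row min/max of half-width ``w`` from the sparse table."""
    m = 2 * w + 1
    j = max(0, int(np.floor(np.log2(m))))
    t = tables[j]
    a = t[:, pad - w : pad - w + width]
    b = t[:, pad + w + 1 - (1 << j) : pad + w + 1 - (1 << j) + width]
    op = np.maximum if maximum else np.minimum
    return op(a, b)


def _vertical_combine(out: np.ndarray, rm: np.ndarray, dy: int, maximum: bool) -> None:
    """In place: out[y] = op(out[y], rm[clamp(y + dy)]) with edge replication."""
    h = out.shape[0]
    op = np.minimum if not maximum else np.maximum
    if dy == 0:
        op(out, rm, out=out)
        return
    if dy > 0:
        op(out[: h - dy], rm[dy:], out=out[: h - dy])
        op(out[h - dy :], rm[-1:], out=out[h - dy :])
    else:
        d = -dy
        op(out[d:], rm[: h - d], out=out[d:])
        op(out[:d], rm[:1], out=out[:d])


def _levels(radius: int, height: float, n_levels: int) -> list[tuple[float, float]]:
    """(disk radius, level height) pairs for the quantized ball profile."""
    if height <= 0 or n_levels <= 1:
        return [(float(radius), 0.0)]
    heights = height * np.arange(n_levels - 1, -1, -1) / (n_levels - 1)
    out = []
    for v in heights:
        r = radius * np.sqrt(max(0.0, 1.0 - (v / height) ** 2))
        out.append((r, float(v)))
    return out


def _ball_filter(f: np.ndarray, radius: int, height: float, n_levels: int, maximum: bool) -> np.ndarray:
    f = np.asarray(f)
    if f.dtype not in (np.float32, np.float64):
        f = f.astype(np.float64)
    h, w = f.shape
    levels = _levels(radius, height, n_levels)
    tables, pad = _build_tables(f, radius, maximum)
    sign = 1.0 if maximum else -1.0
    out = None
    for r, v in levels:
        ri = int(np.floor(r + 1e-9))
        lev = np.full((h, w), -np.inf if maximum else np.inf, dtype=f.dtype)
        for dy in range(ri + 1):  # widths are symmetric in +/- dy
            wdx = int(np.floor(np.sqrt(max(0.0, r * r - dy * dy)) + 1e-9))
            rm = _row_window(tables, pad, w, wdx, maximum)
            _vertical_combine(lev, rm, dy, maximum)
            if dy:
                _vertical_combine(lev, rm, -dy, maximum)
        lev += sign * v
        if out is None:
            out = lev
        else:
            (np.maximum if maximum else np.minimum)(out, lev, out=out)
    return out


def ball_erosion(f: np.ndarray, radius: int, height: float, n_levels: int = 6) -> np.ndarray:
    """Grayscale erosion by the quantized ball SE (see module docstring)."""
    return _ball_filter(f, radius, height, n_levels, maximum=False)


def ball_dilation(f: np.ndarray, radius: int, height: float, n_levels: int = 6) -> np.ndarray:
    """Grayscale dilation by the quantized ball SE."""
    return _ball_filter(f, radius, height, n_levels, maximum=True)


def ball_opening(f: np.ndarray, radius: int, height: float, n_levels: int = 6) -> np.ndarray:
    """Opening (dilation of erosion) by the quantized ball SE."""
    return ball_dilation(ball_erosion(f, radius, height, n_levels), radius, height, n_levels)
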