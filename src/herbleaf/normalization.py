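"""Leaf-pose normalization: tip detection, main-vein tracing, straightening.

The main vein is modeled as the minimal-cost path from the petiole to the
leaf tip through the vein map.  Per-pixel cost combines weak line strength
and misalignment with the base-tip axis g:

    eps(x, y) = (1 - S_norm(x, y)) + delta_alpha(x, y) / 90

where ``S_norm`` is the strength min-max normalized over mask pixels and
``delta_alpha`` is the acute angle (degrees) between the local line
orientation and the direction of g.  Both terms lie in [0, 1], making the
cost nonnegative so an exact shortest-path search applies; path cost is
accumulated geodesic-time style, weighting each move by its Euclidean step
length (1 axial, sqrt(2) diagonal) and the mean cost of its two endpoints.

After tracing, the path is approximated by a cubic ``col = f(row)`` in a
frame rotated so that g is vertical with the tip up, and the image is
straightened by shifting every row so the fitted midvein becomes a
straight vertical line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra

from herbleaf.line_operator import LineMap
from herbleaf.segmentation import BinaryMask

logger = logging.getLogger("herbleaf")

Coord = tuple[int, int]


class NormalizationError(RuntimeError):
    pass


@dataclass
class MidveinPath:
    """Traced main vein from petiole to tip."""

    pixels: list[Coord]  # ordered (row, col), petiole first
    axis_g: tuple[Coord, Coord]  # (petiole, tip)
    delta_alpha: np.ndarray  # per-pixel angle to g, degrees in [0, 90]
    cost: float
    cubic: np.ndarray | None = None  # a0..a3, col(row) in the rotated frame

    @property
    def petiole(self) -> Coord:
        return self.axis_g[0]

    @property
    def tip(self) -> Coord:
        return self.axis_g[1]


@dataclass
class NormalizedLeaf:
    """Leaf image and mask warped so the midvein is a vertical line, tip up."""

    image: np.ndarray
    mask: BinaryMask
    vein_column: int
    base_row: int
    tip_row: int

    def __post_init__(self) -> None:
        if self.tip_row >= self.base_row:
            raise ValueError("tip must be above base after normalization")


# ---------------------------------------------------------------------------
# tip detection
# ---------------------------------------------------------------------------


def detect_tip(
    mask: BinaryMask, petiole: Coord, tip_fraction: float = 0.02
) -> Coord:
    """Locate the leaf tip as the far end of the petiole-through-centroid ray.

    All mask pixels are projected onto the ray from the petiole through the
    mask centroid; the tip region is the outermost ``tip_fraction`` of the
    area by projection, and the returned tip is the region's pixel with the
    largest projection (ties broken toward the smallest row, then column).
    """
    if not 0 < tip_fraction < 0.5:
        raise ValueError("tip_fraction must be in (0, 0.5)")
    grid = mask.grid
    rows, cols = np.nonzero(grid)
    if len(rows) == 0:
        raise NormalizationError("empty mask")
    r0, c0 = petiole
    if not (rows.min() - 1 <= r0 <= rows.max() + 1 and cols.min() - 1 <= c0 <= cols.max() + 1):
        raise NormalizationError(
            f"petiole {petiole} outside the mask bounding box"
        )
    centroid = np.array([rows.mean(), cols.mean()])
    d = centroid - np.array([r0, c0], dtype=float)
    norm = np.hypot(*d)
    if norm == 0:
        raise NormalizationError("petiole coincides with the centroid")
    d /= norm
    proj = (rows - r0) * d[0] + (cols - c0) * d[1]
    cutoff = np.quantile(proj, 1.0 - tip_fraction)
    region = proj > cutoff
    if not region.any():
        region = proj >= cutoff
    # max projection; pixels within half a pixel of the max count as ties
    # (raster quantization), resolved toward the smallest row, then col
    cand = np.flatnonzero(region)
    near_max = cand[proj[cand] >= proj[cand].max() - 0.5]
    order = np.lexsort((cols[near_max], rows[near_max]))
    best = near_max[order[0]]
    return int(rows[best]), int(cols[best])


def default_petiole(mask: BinaryMask) -> Coord:
    """Fallback petiole: the lowest-row extreme point of the mask.

    Among the pixels of the lowest mask row, the central one is taken (an
    off-center base point would tilt the base-tip axis spuriously).
    """
    rows, cols = np.nonzero(mask.grid)
    r = rows.max()
    row_cols = np.sort(cols[rows == r])
    c = row_cols[len(row_cols) // 2]
    return int(r), int(c)


# ---------------------------------------------------------------------------
# geodesic tracing
# ---------------------------------------------------------------------------


def axis_angle(petiole: Coord, tip: Coord) -> float:
    """Orientation of g (petiole -> tip), degrees CCW from the column axis, mod 180."""
    dr = tip[0] - petiole[0]
    dc = tip[1] - petiole[1]
    return float(np.rad2deg(np.arctan2(-dr, dc)) % 180.0)


def delta_alpha_map(linemap: LineMap, petiole: Coord, tip: Coord) -> np.ndarray:
    """Acute angle between O(x, y) and the fixed direction of g, degrees in [0, 90]."""
    g = axis_angle(petiole, tip)
    diff = np.abs(linemap.orientation - g) % 180.0
    return np.minimum(diff, 180.0 - diff)


def vein_cost_map(linemap: LineMap, mask: BinaryMask, petiole: Coord, tip: Coord) -> np.ndarray:
    """Per-pixel cost (1 - S_norm) + delta_alpha/90, both terms in [0, 1]."""
    grid = mask.grid
    s = linemap.strength
    inside = s[grid]
    lo, hi = inside.min(), inside.max()
    s_norm = np.zeros_like(s) if hi <= lo else np.clip((s - lo) / (hi - lo), 0.0, 1.0)
    da = delta_alpha_map(linemap, petiole, tip)
    return (1.0 - s_norm) + da / 90.0


_STEPS = [
    (-1, 0, 1.0), (1, 0, 1.0), (0, -1, 1.0), (0, 1, 1.0),
    (-1, -1, np.sqrt(2)), (-1, 1, np.sqrt(2)),
    (1, -1, np.sqrt(2)), (1, 1, np.sqrt(2)),
]


def path_cost(eps: np.ndarray, pixels: list[Coord]) -> float:
    """Geodesic-time cost of an 8-connected pixel path under a cost raster."""
    total = 0.0
    for (r0, c0), (r1, c1) in zip(pixels[:-1], pixels[1:]):
        step = np.hypot(r1 - r0, c1 - c0)
        total += 0.5 * (eps[r0, c0] + eps[r1, c1]) * step
    return float(total)


def minimal_path(
    eps: np.ndarray, mask_grid: np.ndarray, start: Coord, end: Coord
) -> tuple[list[Coord], float]:
    """Exact minimal-cost 8-connected path inside a mask (Dijkstra).

    Edge weight between neighbors u, v is ``0.5 * (eps[u] + eps[v]) * step``
    with step 1 for axial and sqrt(2) for diagonal moves; eps must be >= 0.
    """
    H, W = eps.shape
    grid = np.asarray(mask_grid, bool)
    if not grid[start] or not grid[end]:
        raise NormalizationError("path endpoints must lie inside the mask")
    node_id = -np.ones((H, W), dtype=np.int64)
    rr, cc = np.nonzero(grid)
    node_id[rr, cc] = np.arange(len(rr))
    n = len(rr)
    rows_l, cols_l, w_l = [], [], []
    for dr, dc, step in _STEPS:
        r2, c2 = rr + dr, cc + dc
        ok = (r2 >= 0) & (r2 < H) & (c2 >= 0) & (c2 < W)
        ok[ok] &= grid[r2[ok], c2[ok]]
        u = node_id[rr[ok], cc[ok]]
        v = node_id[r2[ok], c2[ok]]
        w = 0.5 * (eps[rr[ok], cc[ok]] + eps[r2[ok], c2[ok]]) * step
        rows_l.append(u)
        cols_l.append(v)
        w_l.append(w)
    graph = sparse.csr_matrix(
        (np.concatenate(w_l), (np.concatenate(rows_l), np.concatenate(cols_l))),
        shape=(n, n),
    )
    s_idx = int(node_id[start])
    e_idx = int(node_id[end])
    dist, pred = dijkstra(
        graph, directed=True, indices=s_idx, return_predecessors=True
    )
    if not np.isfinite(dist[e_idx]):
        raise NormalizationError("tip unreachable within mask (disconnected?)")
    order = []
    i = e_idx
    while i != s_idx:
        order.append(i)
        i = pred[i]
    order.append(s_idx)
    order.reverse()
    path = [(int(rr[i]), int(cc[i])) for i in order]
    return path, float(dist[e_idx])


def trace_main_vein(
    linemap: LineMap, mask: BinaryMask, petiole: Coord, tip: Coord
) -> MidveinPath:
    """Trace the main vein as the minimal-cost path from petiole to tip."""
    if linemap.shape != mask.shape:
        raise ValueError("linemap and mask must share shape")
    eps = vein_cost_map(linemap, mask, petiole, tip)
    pixels, cost = minimal_path(eps, mask.grid, petiole, tip)
    return MidveinPath(
        pixels=pixels,
        axis_g=(tuple(petiole), tuple(tip)),
        delta_alpha=delta_alpha_map(linemap, petiole, tip),
        cost=cost,
    )


# ---------------------------------------------------------------------------
# cubic fit and straightening
# ---------------------------------------------------------------------------


def rotation_to_vertical(petiole: Coord, tip: Coord) -> np.ndarray:
    """2x2 rotation mapping (p - petiole) so that the tip lies straight above.

    In the rotated frame the petiole is at the origin and the tip at
    (-|g|, 0): rows decrease toward the tip ("tip up").
    """
    g = np.array([tip[0] - petiole[0], tip[1] - petiole[1]], dtype=float)
    norm = np.hypot(*g)
    if norm == 0:
        raise NormalizationError("petiole and tip coincide")
    u = g / norm
    target = np.array([-1.0, 0.0])
    # R @ u == target; rotation by the signed angle between them
    cos = float(u @ target)
    sin = float(u[0] * target[1] - u[1] * target[0])
    return np.array([[cos, -sin], [sin, cos]])


def fit_midvein_cubic(path: MidveinPath) -> np.ndarray:
    """Least-squares cubic col = a0 + a1*r + a2*r^2 + a3*r^3 in the rotated frame."""
    pts = np.asarray(path.pixels, dtype=float)
    if len(pts) < 4:
        raise NormalizationError("need at least 4 path pixels for a cubic fit")
    R = rotation_to_vertical(path.petiole, path.tip)
    q = (pts - np.asarray(path.petiole, float)) @ R.T
    rows, cols = q[:, 0], q[:, 1]
    if len(np.unique(np.round(rows, 6))) < 4:
        raise NormalizationError("path spans fewer than 4 distinct rows")
    coeffs = np.polynomial.polynomial.polyfit(rows, cols, 3)
    path.cubic = coeffs
    return coeffs


def _eval_cubic(coeffs: np.ndarray, rows: np.ndarray) -> np.ndarray:
    return np.polynomial.polynomial.polyval(rows, coeffs)


def straighten(
    image: np.ndarray,
    mask: BinaryMask,
    petiole: Coord,
    tip: Coord,
    cubic: np.ndarray,
    pad: int = 2,
) -> NormalizedLeaf:
    """Rotate g vertical (tip up) and shift each row so the midvein is straight.

    The combined warp maps an input pixel p through the rotated frame
    q = R (p - petiole), then moves row q_r horizontally so that the fitted
    midvein column ``cubic(q_r)`` lands on a fixed output column.  The
    output canvas is sized so no mask pixel is lost; image resampling is
    bilinear, mask resampling nearest-neighbor, and out-of-canvas pixels
    take the median background (non-mask) intensity.
    """
    img = np.asarray(image, dtype=np.float64)
    grid = mask.grid
    if img.shape[:2] != grid.shape:
        raise ValueError("image and mask must share shape")
    R = rotation_to_vertical(petiole, tip)
    p0 = np.asarray(petiole, dtype=float)

    rr, cc = np.nonzero(grid)
    pts = np.stack([rr, cc], axis=1).astype(float)
    q = (pts - p0) @ R.T
    q_rows, q_cols = q[:, 0], q[:, 1]
    shifted_cols = q_cols - _eval_cubic(cubic, q_rows)

    t_r = pad - np.floor(q_rows.min())
    vein_column = int(pad - np.floor(shifted_cols.min()))
    H_out = int(np.ceil(q_rows.max() + t_r)) + 1 + pad
    W_out = int(np.ceil(shifted_cols.max() + vein_column)) + 1 + pad

    out_r, out_c = np.meshgrid(
        np.arange(H_out), np.arange(W_out), indexing="ij"
    )
    src_qr = out_r - t_r
    src_qc = out_c - vein_column + _eval_cubic(cubic, src_qr)
    src = np.stack([src_qr.ravel(), src_qc.ravel()], axis=1) @ R + p0
    coords = [src[:, 0].reshape(H_out, W_out), src[:, 1].reshape(H_out, W_out)]

    bg = float(np.median(img[~grid])) if (~grid).any() else 0.0
    if img.ndim == 3:
        warped = np.stack(
            [
                ndimage.map_coordinates(img[..., ch], coords, order=1, cval=bg, mode="constant")
                for ch in range(img.shape[2])
            ],
            axis=-1,
        )
    else:
        warped = ndimage.map_coordinates(img, coords, order=1, cval=bg, mode="constant")
    # bilinear on the float mask + 0.5 threshold keeps the boundary at
    # subpixel accuracy (plain nearest-neighbor erodes ~0.5 px per warp)
    warped_mask = ndimage.map_coordinates(
        grid.astype(np.float64), coords, order=1, cval=0.0, mode="constant"
    ) >= 0.5

    q_pet = np.array([0.0, 0.0])
    q_tip = R @ (np.asarray(tip, float) - p0)
    base_row = int(round(q_pet[0] + t_r))
    tip_row = int(round(q_tip[0] + t_r))
    return NormalizedLeaf(
        image=warped,
        mask=BinaryMask(warped_mask),
        vein_column=vein_column,
        base_row=base_row,
        tip_row=tip_row,
    )
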