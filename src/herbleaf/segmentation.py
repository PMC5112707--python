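"""Scribble-seeded binary graph-cut segmentation (lazy-snapping style).

A user (or the synthetic generator) marks a few foreground and background
pixels; per-side k-means color models supply per-pixel data terms and a
4-connected contrast-modulated smoothness term; the resulting binary
submodular energy is minimized exactly by an s-t minimum cut:

    E(L) = sum_i D_i(L_i) + lambda * sum_{(i,j) in N4} [L_i != L_j] / (1 + ||c_i - c_j||)

with D_i(FG) = d_fg / (d_fg + d_bg) (nearest-cluster color distances) and
scribbled pixels given hard labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import breadth_first_order, maximum_flow
from sklearn.cluster import KMeans

from herbleaf.dataset_io import SCRIBBLE_BG, SCRIBBLE_FG

logger = logging.getLogger("herbleaf")


class SegmentationError(RuntimeError):
    pass


@dataclass
class ColorModel:
    """Per-side k-means cluster centers in color space."""

    fg_centers: np.ndarray  # (n_fg, 3)
    bg_centers: np.ndarray  # (n_bg, 3)
    K: int

    def __post_init__(self) -> None:
        self.fg_centers = np.atleast_2d(np.asarray(self.fg_centers, dtype=np.float64))
        self.bg_centers = np.atleast_2d(np.asarray(self.bg_centers, dtype=np.float64))
        if not (1 <= len(self.fg_centers) <= self.K):
            raise ValueError("need 1..K foreground centers")
        if not (1 <= len(self.bg_centers) <= self.K):
            raise ValueError("need 1..K background centers")


@dataclass
class BinaryMask:
    """Boolean foreground raster."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def area(self) -> int:
        return int(self.grid.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


def _as_color(image: np.ndarray) -> np.ndarray:
    """Return an (H, W, 3) float view; grayscale becomes 3 equal channels."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("image must be 2-D grayscale or 3-channel")
    return img


def fit_color_model(image: np.ndarray, scribbles: np.ndarray, K: int = 8) -> ColorModel:
    """Cluster scribbled foreground and background colors with k-means.

    If a side has fewer distinct colors than ``K``, fewer centers are
    returned (one per distinct color).
    """
    img = _as_color(image)
    scr = np.asarray(scribbles)
    if scr.shape != img.shape[:2]:
        raise ValueError("scribbles shape must match image")
    fg = img[scr == SCRIBBLE_FG]
    bg = img[scr == SCRIBBLE_BG]
    if len(fg) == 0:
        raise SegmentationError("no foreground scribbles found")
    if len(bg) == 0:
        raise SegmentationError("no background scribbles found")
    return ColorModel(_centers(fg, K), _centers(bg, K), K=K)


def _centers(colors: np.ndarray, K: int) -> np.ndarray:
    distinct = np.unique(colors, axis=0)
    k = min(K, len(distinct))
    if k == len(distinct):
        return distinct
    km = KMeans(n_clusters=k, n_init=5, random_state=0)
    km.fit(colors)
    # deterministic order
    order = np.lexsort(km.cluster_centers_.T[::-1])
    return km.cluster_centers_[order]


def data_terms(image: np.ndarray, model: ColorModel) -> np.ndarray:
    """Normalized nearest-cluster data terms, shape (H, W, 2).

    ``[..., 0]`` is the cost of labeling a pixel background,
    ``[..., 1]`` the cost of labeling it foreground.
    """
    img = _as_color(image)
    flat = img.reshape(-1, 3)
    d_fg = np.sqrt(
        ((flat[:, None, :] - model.fg_centers[None, :, :]) ** 2).sum(-1)
    ).min(1)
    d_bg = np.sqrt(
        ((flat[:, None, :] - model.bg_centers[None, :, :]) ** 2).sum(-1)
    ).min(1)
    denom = d_fg + d_bg
    with np.errstate(invalid="ignore"):
        cost_fg = np.where(denom > 0, d_fg / denom, 0.5)
    out = np.stack([1.0 - cost_fg, cost_fg], axis=-1)
    return out.reshape(img.shape[0], img.shape[1], 2)


def smoothness_weights(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Contrast weights 1/(1+||c_i-c_j||) for vertical and horizontal 4-neighbor pairs.

    Returns ``(w_v, w_h)`` with shapes (H-1, W) and (H, W-1).
    """
    img = _as_color(image)
    dv = np.sqrt(((img[1:, :] - img[:-1, :]) ** 2).sum(-1))
    dh = np.sqrt(((img[:, 1:] - img[:, :-1]) ** 2).sum(-1))
    return 1.0 / (1.0 + dv), 1.0 / (1.0 + dh)


def labeling_energy(
    D: np.ndarray,
    w_v: np.ndarray,
    w_h: np.ndarray,
    labels: np.ndarray,
    lambda_smooth: float,
) -> float:
    """Energy of an arbitrary binary labeling under the segmentation model."""
    lab = np.asarray(labels, dtype=int)
    data = np.take_along_axis(D, lab[:, :, None], axis=2)[:, :, 0].sum()
    disc_v = (lab[1:, :] != lab[:-1, :]) * w_v
    disc_h = (lab[:, 1:] != lab[:, :-1]) * w_h
    return float(data + lambda_smooth * (disc_v.sum() + disc_h.sum()))


def min_cut_labeling(
    D: np.ndarray,
    w_v: np.ndarray,
    w_h: np.ndarray,
    lambda_smooth: float,
    hard_fg: np.ndarray | None = None,
    hard_bg: np.ndarray | None = None,
) -> np.ndarray:
    """Exact global minimizer of the binary energy via s-t minimum cut.

    Capacities are scaled to integers for :func:`scipy.sparse.csgraph.maximum_flow`;
    the scale is chosen so the total flow stays well inside int32 while the
    rounding granularity stays negligible relative to the energy landscape.
    """
    H, W = D.shape[:2]
    n = H * W
    if lambda_smooth < 0:
        raise ValueError("lambda_smooth must be >= 0")
    idx = np.arange(n).reshape(H, W)

    cap_bg = D[:, :, 0].astype(np.float64).ravel()  # cut when pixel labeled BG
    cap_fg = D[:, :, 1].astype(np.float64).ravel()  # cut when pixel labeled FG
    big = cap_bg.sum() + cap_fg.sum() + lambda_smooth * (w_v.sum() + w_h.sum()) + 1.0
    if hard_fg is not None:
        hf = np.asarray(hard_fg, bool).ravel()
        cap_bg = np.where(hf, big, cap_bg)
        cap_fg = np.where(hf, 0.0, cap_fg)
    if hard_bg is not None:
        hb = np.asarray(hard_bg, bool).ravel()
        if hard_fg is not None and np.any(hb & np.asarray(hard_fg, bool).ravel()):
            raise SegmentationError("pixel scribbled both foreground and background")
        cap_fg = np.where(hb, big, cap_fg)
        cap_bg = np.where(hb, 0.0, cap_bg)

    # pairwise capacities (both directions)
    pv = lambda_smooth * w_v
    ph = lambda_smooth * w_h
    max_total = cap_bg.sum() + 1.0  # max flow bounded by source-side capacity
    scale = (2**30) / max(max_total, 1.0)

    def q(x):
        # any capacity >= the total possible flow (<= 2^30 after scaling)
        # acts as infinite; clipping keeps everything inside int32
        return np.minimum(
            np.rint(np.asarray(x) * scale).astype(np.int64), 2**30
        )

    src, dst = n, n + 1
    rows, cols, caps = [], [], []
    # terminal links: source->i cut when i is BG, i->sink cut when i is FG
    rows.append(np.full(n, src))
    cols.append(np.arange(n))
    caps.append(q(cap_bg))
    rows.append(np.arange(n))
    cols.append(np.full(n, dst))
    caps.append(q(cap_fg))
    if lambda_smooth > 0:
        a, b = idx[:-1, :].ravel(), idx[1:, :].ravel()
        wq = q(pv.ravel())
        rows += [a, b]
        cols += [b, a]
        caps += [wq, wq]
        a, b = idx[:, :-1].ravel(), idx[:, 1:].ravel()
        wq = q(ph.ravel())
        rows += [a, b]
        cols += [b, a]
        caps += [wq, wq]
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    caps = np.concatenate(caps)
    keep = caps > 0
    graph = sparse.csr_matrix(
        (caps[keep].astype(np.int32), (rows[keep], cols[keep])), shape=(n + 2, n + 2)
    )
    result = maximum_flow(graph, src, dst)
    residual = graph - result.flow
    residual.eliminate_zeros()
    reachable = breadth_first_order(
        residual > 0, src, directed=True, return_predecessors=False
    )
    labels = np.zeros(n, dtype=bool)
    labels[reachable[reachable < n]] = True  # source side = foreground
    return labels.reshape(H, W)


def lazy_snap(
    image: np.ndarray,
    scribbles: np.ndarray,
    K: int = 8,
    lambda_smooth: float = 10.0,
) -> BinaryMask:
    """Segment the scribbled foreground object with an exact graph cut."""
    model = fit_color_model(image, scribbles, K)
    D = data_terms(image, model)
    w_v, w_h = smoothness_weights(image)
    scr = np.asarray(scribbles)
    labels = min_cut_labeling(
        D, w_v, w_h, lambda_smooth,
        hard_fg=scr == SCRIBBLE_FG,
        hard_bg=scr == SCRIBBLE_BG,
    )
    if not labels.any():
        raise SegmentationError(
            "segmentation produced an empty mask; add more foreground scribbles"
        )
    return BinaryMask(labels)


def cleanup_mask(mask: BinaryMask) -> BinaryMask:
    """Keep the largest 4-connected component; fill holes < 0.1% of its area."""
    grid = mask.grid
    if not grid.any():
        raise SegmentationError("cannot clean an empty mask")
    labels, n = ndimage.label(grid)  # default structure = 4-connectivity
    if n > 1:
        sizes = ndimage.sum_labels(grid, labels, index=np.arange(1, n + 1))
        labels = labels == (1 + int(np.argmax(sizes)))
    else:
        labels = labels.astype(bool)
    area = labels.sum()
    # holes: 8-connected background components not touching the border
    bg_labels, n_bg = ndimage.label(~labels, structure=np.ones((3, 3), dtype=int))
    border = np.zeros_like(labels, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_ids = set(np.unique(bg_labels[border])) - {0}
    out = labels.copy()
    for i in range(1, n_bg + 1):
        if i in border_ids:
            continue
        hole = bg_labels == i
        if hole.sum() < 0.001 * area:
            out |= hole
    return BinaryMask(out)
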