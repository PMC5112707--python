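"""Feature extraction from a normalized leaf.

Three blocks are produced:

* ``fs1`` — 20 Fourier descriptors of the mask outline, normalized to be
  invariant under translation, rotation, uniform scaling and the choice of
  contour starting point;
* ``fs2`` — nine classical shape descriptors (compactness, convexity,
  solidity, rectangularity, circularity, perimeter-area ratio, slimness,
  position of maximum thickness, dispersion);
* ``fs3`` — strength-weighted vein-orientation histograms: one histogram
  for the upper and one for the lower half of the leaf, each obtained by
  averaging the left side with the mirrored right side and normalizing to
  unit sum.  2 x 24 bins = 48 values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage import measure

from herbleaf.config import PipelineConfig
from herbleaf.line_operator import LineMap, line_response_multiscale
from herbleaf.normalization import NormalizedLeaf
from herbleaf.segmentation import BinaryMask

logger = logging.getLogger("herbleaf")

FS2_NAMES = (
    "compactness",
    "convexity",
    "solidity",
    "rectangularity",
    "circularity",
    "perimeter_area_ratio",
    "slimness",
    "max_thickness_position",
    "dispersion",
)

#: number of equally spaced contour samples used for FS1 and perimeter measures
N_CONTOUR_SAMPLES = 256


class FeatureError(RuntimeError):
    pass


@dataclass
class FeatureVector:
    """Concatenated feature blocks with block identity retained."""

    fs1: np.ndarray
    fs2: np.ndarray
    fs3: np.ndarray

    def __post_init__(self) -> None:
        self.fs1 = np.asarray(self.fs1, dtype=np.float64)
        self.fs2 = np.asarray(self.fs2, dtype=np.float64)
        self.fs3 = np.asarray(self.fs3, dtype=np.float64)

    @property
    def blocks(self) -> dict[str, np.ndarray]:
        return {"fs1": self.fs1, "fs2": self.fs2, "fs3": self.fs3}

    def concat(self, names: tuple[str, ...] = ("fs1", "fs2", "fs3")) -> np.ndarray:
        bad = [n for n in names if n not in self.blocks]
        if bad:
            raise KeyError(f"unknown feature block(s): {bad}")
        return np.concatenate([self.blocks[n] for n in names])

    def __len__(self) -> int:
        return len(self.fs1) + len(self.fs2) + len(self.fs3)


# ---------------------------------------------------------------------------
# contour helpers
# ---------------------------------------------------------------------------


def outer_contour(mask: BinaryMask, n_samples: int = N_CONTOUR_SAMPLES) -> np.ndarray:
    """Outer mask boundary resampled to equally spaced arc-length points.

    Returns an (n_samples, 2) array of (row, col) positions tracing the
    closed contour; the mask must have a single connected component.
    """
    grid = mask.grid
    n_comp = ndimage.label(grid, structure=np.ones((3, 3), dtype=int))[1]
    if n_comp != 1:
        raise FeatureError(f"mask must have exactly one component (found {n_comp})")
    contours = measure.find_contours(grid.astype(float), 0.5)
    if not contours:
        raise FeatureError("no contour found")
    contour = max(contours, key=len)
    if len(contour) < 8:
        raise FeatureError("contour too short")
    if not np.allclose(contour[0], contour[-1]):
        contour = np.vstack([contour, contour[0]])
    seg = np.sqrt(((np.diff(contour, axis=0)) ** 2).sum(1))
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    if total <= 0:
        raise FeatureError("degenerate contour")
    targets = np.linspace(0.0, total, n_samples, endpoint=False)
    rows = np.interp(targets, arclen, contour[:, 0])
    cols = np.interp(targets, arclen, contour[:, 1])
    return np.stack([rows, cols], axis=1)


def contour_perimeter(points: np.ndarray) -> float:
    closed = np.vstack([points, points[0]])
    return float(np.sqrt(((np.diff(closed, axis=0)) ** 2).sum(1)).sum())


def smooth_closed_contour(points: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Circular Gaussian smoothing of contour samples.

    Corrects the raster staircase bias of marching-squares contours, which
    otherwise inflates perimeter estimates by several percent.
    """
    return np.stack(
        [
            ndimage.gaussian_filter1d(points[:, 0], sigma, mode="wrap"),
            ndimage.gaussian_filter1d(points[:, 1], sigma, mode="wrap"),
        ],
        axis=1,
    )


# ---------------------------------------------------------------------------
# FS1 — Fourier descriptors
# ---------------------------------------------------------------------------


def resample_closed_contour(points: np.ndarray, n_samples: int) -> np.ndarray:
    """Resample a closed polygon to equally spaced arc-length points."""
    pts = np.asarray(points, dtype=float)
    if not np.allclose(pts[0], pts[-1]):
        pts = np.vstack([pts, pts[0]])
    seg = np.sqrt(((np.diff(pts, axis=0)) ** 2).sum(1))
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    if total <= 0:
        raise FeatureError("degenerate contour")
    targets = np.linspace(0.0, total, n_samples, endpoint=False)
    return np.stack(
        [np.interp(targets, arclen, pts[:, 0]), np.interp(targets, arclen, pts[:, 1])],
        axis=1,
    )


def fourier_descriptors_from_contour(points: np.ndarray, n_desc: int = 20) -> np.ndarray:
    """Invariant Fourier descriptors of a closed contour polygon.

    The contour is resampled to :data:`N_CONTOUR_SAMPLES` equal arc-length
    points as complex numbers ``col + i * row``.  Descriptors are the DFT
    magnitudes at frequencies ``{-n/2 .. -1}`` and ``{2 .. n/2 + 1}``
    divided by the magnitude at frequency 1: dropping coefficient 0 gives
    translation invariance, taking magnitudes gives rotation/start-point
    invariance, and the division gives scale invariance.
    """
    if n_desc < 2 or n_desc % 2:
        raise ValueError("n_desc must be even and >= 2")
    pts = np.asarray(points, dtype=float)
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    # canonical start vertex (farthest from the centroid): the resampling
    # phase then does not depend on where the input contour happens to
    # begin, making start-point invariance exact
    start = int(np.argmax(((pts - pts.mean(axis=0)) ** 2).sum(axis=1)))
    pts = resample_closed_contour(np.roll(pts, -start, axis=0), N_CONTOUR_SAMPLES)
    pts = smooth_closed_contour(pts, sigma=1.5)
    if len(pts) < n_desc + 2:
        raise FeatureError("contour too short for requested descriptor count")
    z = pts[:, 1] + 1j * pts[:, 0]
    F = np.fft.fft(z) / len(z)
    fund = np.abs(F[1])
    if fund == 0:
        raise FeatureError("degenerate contour (no fundamental frequency)")
    half = n_desc // 2
    freqs = list(range(-half, 0)) + list(range(2, half + 2))
    return np.abs(F[np.array(freqs)]) / fund


def fourier_descriptors(mask: BinaryMask, n_desc: int = 20) -> np.ndarray:
    """Invariant Fourier descriptors of a mask's outer boundary."""
    return fourier_descriptors_from_contour(outer_contour(mask), n_desc)


# ---------------------------------------------------------------------------
# FS2 — classical shape descriptors
# ---------------------------------------------------------------------------


def _min_area_rect(points: np.ndarray) -> float:
    """Area of the minimum-area enclosing rectangle (rotating calipers)."""
    hull = ConvexHull(points)
    hp = points[hull.vertices]
    edges = np.diff(np.vstack([hp, hp[0]]), axis=0)
    angles = np.arctan2(edges[:, 0], edges[:, 1])
    best = np.inf
    for ang in np.unique(np.mod(angles, np.pi / 2)):
        c, s = np.cos(ang), np.sin(ang)
        rot = hp @ np.array([[c, -s], [s, c]])
        extent = rot.max(0) - rot.min(0)
        best = min(best, float(extent[0] * extent[1]))
    return best


def shape_descriptors(
    mask: BinaryMask,
    base_row: int | None = None,
    tip_row: int | None = None,
) -> np.ndarray:
    """Nine region-shape descriptors (see :data:`FS2_NAMES` for the order).

    The mask is expected in the normalized frame (tip up) for the
    axis-dependent measures; ``base_row``/``tip_row`` default to the mask's
    bounding-box extremes.
    """
    grid = mask.grid
    area = float(grid.sum())
    if area <= 0:
        raise FeatureError("zero-area mask")
    pts = smooth_closed_contour(outer_contour(mask))
    perim = contour_perimeter(pts)

    hull = ConvexHull(pts)
    hull_pts = pts[hull.vertices]
    hull_perim = contour_perimeter(hull_pts)
    hull_area = float(hull.volume)

    rows, cols = np.nonzero(grid)
    centroid = np.array([rows.mean(), cols.mean()])
    radial = np.sqrt(((pts - centroid) ** 2).sum(1))
    mu_r, sigma_r = float(radial.mean()), float(radial.std())
    if sigma_r == 0:
        raise FeatureError("degenerate radial distribution")

    r_min, r_max = int(rows.min()), int(rows.max())
    c_min, c_max = int(cols.min()), int(cols.max())
    height = r_max - r_min + 1
    width = c_max - c_min + 1
    if base_row is None:
        base_row = r_max
    if tip_row is None:
        tip_row = r_min
    span = max(base_row - tip_row, 1)
    widths = grid.sum(axis=1)
    widest_row = int(np.argmax(widths))
    thickness_pos = float(np.clip((base_row - widest_row) / span, 0.0, 1.0))

    return np.array(
        [
            4.0 * np.pi * area / perim**2,  # compactness
            hull_perim / perim,  # convexity
            area / hull_area,  # solidity
            area / _min_area_rect(pts),  # rectangularity
            mu_r / sigma_r,  # circularity
            perim / area,  # perimeter-area ratio
            width / height,  # slimness
            thickness_pos,  # position of maximum thickness
            radial.max() / mu_r,  # dispersion
        ]
    )


# ---------------------------------------------------------------------------
# FS3 — strength-weighted orientation histograms
# ---------------------------------------------------------------------------


def _orientation_bins(linemap: LineMap, n_bins: int) -> np.ndarray:
    width = 180.0 / n_bins
    return np.rint(linemap.orientation / width).astype(int) % n_bins


def mirror_histogram(hist: np.ndarray) -> np.ndarray:
    """Map the bin for angle theta to the bin for 180 - theta."""
    n = len(hist)
    out = np.empty_like(hist)
    idx = (n - np.arange(n)) % n
    out[:] = hist[idx]
    return out


def orientation_histograms(
    linemap: LineMap,
    normleaf: NormalizedLeaf,
    n_bins: int = 24,
    normalize: bool = True,
    margin_erosion: int = 3,
    strength_quantile: float = 0.75,
    vein_band: int = 2,
) -> np.ndarray:
    """Upper- and lower-half vein orientation histograms (concatenated, 2 x n_bins).

    Each accumulated pixel contributes ``max(S, 0)`` to its orientation
    bin.  The leaf is split into upper/lower halves at the row midway
    between tip and base and into left/right of the vein column;
    right-side histograms are mirrored and averaged with the left.

    The accumulation domain excludes three kinds of pixels that carry no
    venation signal: a ``margin_erosion``-pixel rim (the outline edge
    response), a ``vein_band``-column strip around the straightened midvein
    (identical for every normalized leaf), and pixels whose strength falls
    below the ``strength_quantile`` of in-mask strengths (diffuse near-vein
    clutter).  Set the last three arguments to zero to accumulate every
    mask pixel.
    """
    if n_bins != linemap.n_orientations:
        raise ValueError("n_bins must equal the linemap's n_orientations")
    grid = normleaf.mask.grid
    if linemap.shape != grid.shape:
        raise ValueError("linemap and normalized mask must share shape")
    if margin_erosion > 0:
        grid = ndimage.binary_erosion(grid, iterations=margin_erosion)
    weights = np.maximum(linemap.strength, 0.0)
    rr, cc = np.indices(grid.shape)
    if vein_band > 0:
        grid = grid & (np.abs(cc - normleaf.vein_column) > vein_band)
    if strength_quantile > 0 and grid.any():
        grid = grid & (weights >= np.quantile(weights[grid], strength_quantile))
    bins = _orientation_bins(linemap, n_bins)
    mid_row = 0.5 * (normleaf.tip_row + normleaf.base_row)
    upper = grid & (rr < mid_row)
    lower = grid & (rr >= mid_row)
    out = []
    for half_name, half in (("upper", upper), ("lower", lower)):
        left = half & (cc < normleaf.vein_column)
        right = half & (cc > normleaf.vein_column)
        h_left = np.bincount(bins[left], weights=weights[left], minlength=n_bins)
        h_right = np.bincount(bins[right], weights=weights[right], minlength=n_bins)
        hist = 0.5 * (h_left + mirror_histogram(h_right))
        total = hist.sum()
        if total == 0:
            logger.warning("empty %s half: zero orientation histogram", half_name)
        elif normalize:
            hist = hist / total
        out.append(hist)
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------


def extract_all(normleaf: NormalizedLeaf, config: PipelineConfig) -> FeatureVector:
    """Extract FS1 + FS2 + FS3 from a normalized leaf (deterministic)."""
    img = normleaf.image
    if img.ndim == 3:
        img = img.mean(axis=2)
    linemap = line_response_multiscale(
        img,
        n_orientations=config.n_orientations,
        template_length=config.template_length,
        n_scales=config.n_scales,
    )
    fs1 = fourier_descriptors(normleaf.mask, config.n_fourier)
    fs2 = shape_descriptors(normleaf.mask, normleaf.base_row, normleaf.tip_row)
    fs3 = orientation_histograms(
        linemap,
        normleaf,
        config.n_hist_bins,
        normalize=config.normalize_histograms,
        strength_quantile=config.fs3_strength_quantile,
    )
    return FeatureVector(fs1=fs1, fs2=fs2, fs3=fs3)
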