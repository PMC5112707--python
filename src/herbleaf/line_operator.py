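"""Multi-scale oriented line operator producing vein strength and orientation maps.

For every pixel, a straight line template of ``template_length`` samples is
evaluated at ``n_orientations`` evenly spaced angles in [0, 180); the
response of an angle is the mean intensity of the surrounding
``template_length`` x ``template_length`` square minus the mean intensity
along the line (dark lines on a light background score positive).  The
strongest response over angles gives the strength S(x, y), its angle the
orientation O(x, y).  Multi-scale detection repeats this on a Gaussian
pyramid and keeps, per pixel, the scale with maximal strength.

Angles are measured counterclockwise from the image x-axis (columns),
modulo 180 degrees, so a vertical line has orientation 90.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

logger = logging.getLogger("herbleaf")


@dataclass
class LineMap:
    """Per-pixel line strength and orientation."""

    strength: np.ndarray  # S(x, y), >= comparable across pixels of one image
    orientation: np.ndarray  # O(x, y), degrees in [0, 180)
    n_orientations: int
    scales_used: int = 1

    def __post_init__(self) -> None:
        self.strength = np.asarray(self.strength, dtype=np.float64)
        self.orientation = np.asarray(self.orientation, dtype=np.float64)
        if self.strength.shape != self.orientation.shape:
            raise ValueError("strength and orientation must share shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.strength.shape


def orientation_angles(n_orientations: int) -> np.ndarray:
    """The evenly spaced template angles (= orientation bin centers), degrees."""
    return np.arange(n_orientations) * (180.0 / n_orientations)


def direction_vector(angle_deg: float) -> tuple[float, float]:
    """Unit step (d_row, d_col) for an angle measured CCW from the column axis."""
    rad = np.deg2rad(angle_deg)
    return -float(np.sin(rad)), float(np.cos(rad))


def _line_kernel(angle_deg: float, template_length: int) -> np.ndarray:
    """Correlation kernel equivalent to bilinear sampling along the rotated line."""
    half = template_length // 2
    size = template_length + 2  # room for bilinear spill
    if size % 2 == 0:
        size += 1
    c = size // 2
    kernel = np.zeros((size, size))
    dr, dc = direction_vector(angle_deg)
    for k in range(-half, half + 1):
        r, col = k * dr, k * dc
        r0, c0 = int(np.floor(r)), int(np.floor(col))
        fr, fc = r - r0, col - c0
        for (ri, ci, w) in (
            (r0, c0, (1 - fr) * (1 - fc)),
            (r0 + 1, c0, fr * (1 - fc)),
            (r0, c0 + 1, (1 - fr) * fc),
            (r0 + 1, c0 + 1, fr * fc),
        ):
            if w > 0:
                kernel[c + ri, c + ci] += w
    return kernel / template_length


def line_response_single_scale(
    gray: np.ndarray,
    n_orientations: int = 24,
    template_length: int = 15,
) -> LineMap:
    """Oriented line responses at the image's native resolution."""
    img = np.asarray(gray, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("line operator expects a single-channel image")
    if template_length < 3 or template_length % 2 == 0:
        raise ValueError("template_length must be odd and >= 3")
    if n_orientations < 2:
        raise ValueError("n_orientations must be >= 2")
    if min(img.shape) < template_length:
        raise ValueError(
            f"image {img.shape} smaller than template length {template_length}"
        )
    square_mean = ndimage.uniform_filter(img, size=template_length, mode="nearest")
    angles = orientation_angles(n_orientations)
    best_s = np.full(img.shape, -np.inf)
    best_a = np.zeros(img.shape, dtype=int)
    for i, ang in enumerate(angles):
        line_mean = ndimage.correlate(
            img, _line_kernel(ang, template_length), mode="nearest"
        )
        resp = square_mean - line_mean  # dark line on light background -> positive
        better = resp > best_s  # strict: ties stay with the smallest angle
        best_s[better] = resp[better]
        best_a[better] = i
    return LineMap(
        strength=best_s,
        orientation=angles[best_a],
        n_orientations=n_orientations,
        scales_used=1,
    )


def line_response_multiscale(
    gray: np.ndarray,
    n_orientations: int = 24,
    template_length: int = 15,
    n_scales: int = 3,
) -> LineMap:
    """Line responses on a Gaussian pyramid, combined by per-pixel max strength.

    Pyramid levels are built by Gaussian smoothing (sigma = 1) followed by
    factor-2 subsampling; coarse responses are upsampled back to full
    resolution (strength bilinearly, orientation nearest-neighbor).  If the
    image is too small for the requested number of levels the count is
    reduced with a warning.
    """
    img = np.asarray(gray, dtype=np.float64)
    if n_scales < 1:
        raise ValueError("n_scales must be >= 1")
    full_shape = img.shape
    best: LineMap | None = None
    level_img = img
    used = 0
    for level in range(n_scales):
        if min(level_img.shape) < template_length:
            if used == 0:
                raise ValueError("image smaller than template at base scale")
            logger.warning(
                "image too small for %d pyramid levels; using %d", n_scales, used
            )
            break
        lm = line_response_single_scale(level_img, n_orientations, template_length)
        if level == 0:
            strength, orientation = lm.strength, lm.orientation
        else:
            strength = resize(
                lm.strength, full_shape, order=1, mode="edge", anti_aliasing=False
            )
            orientation = resize(
                lm.orientation, full_shape, order=0, mode="edge", anti_aliasing=False
            )
        if best is None:
            best = LineMap(strength, orientation, n_orientations)
        else:
            win = strength > best.strength
            best.strength[win] = strength[win]
            best.orientation[win] = orientation[win]
        used += 1
        level_img = ndimage.gaussian_filter(level_img, sigma=1.0, mode="nearest")[::2, ::2]
    assert best is not None
    best.scales_used = used
    return best
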