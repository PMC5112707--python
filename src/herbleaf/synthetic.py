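"""Parametric leaf-image generator with ground truth.

Renders grayscale leaves on a light background: a lamina bounded by a
species-specific half-width profile swept along a (possibly curved)
midvein, a dark midvein, and dark secondary veins leaving the midvein at
species-specific angles that may differ between the lower and the upper
half of the leaf.  Gaussian noise, "herbivore bite" damage and a second
overlapping leaf can be added.  Everything is reproducible from
``(spec, seed)`` and all ground truth (mask, midvein path, petiole) is
returned, so the full pipeline can be validated without any real scans.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.draw import disk as draw_disk

from herbleaf.dataset_io import LeafRecord, Manifest, write_image, write_manifest, write_mask

logger = logging.getLogger("herbleaf")

OUTLINE_FAMILIES = ("elliptic", "obovate", "cordate", "lobed")

BG_LEVEL = 0.85
LAMINA_LEVEL = 0.55
VEIN_LEVEL = 0.25
MIDVEIN_LEVEL = 0.20


@dataclass
class LeafSpec:
    """Parametric description of one synthetic species' leaves."""

    species_name: str
    outline: str = "elliptic"  # one of OUTLINE_FAMILIES
    length_px: int = 160
    width_px: int = 80  # full width at the widest point
    lobe_count: int = 0
    lobe_depth: float = 0.0  # fraction of half-width removed between lobes
    secondary_vein_angle_lower: float = 50.0  # degrees from the midvein
    secondary_vein_angle_upper: float = 50.0
    vein_spacing_px: int = 14
    midvein_curvature: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    tilt_deg: float = 0.0  # whole-leaf rotation (pressing/mounting pose)
    noise_sd: float = 0.02
    damage_fraction: float = 0.0
    overlap: tuple[int, int] | None = None  # (row, col) offset of a second leaf

    def __post_init__(self) -> None:
        if self.outline not in OUTLINE_FAMILIES:
            raise ValueError(f"unknown outline family {self.outline!r}")
        if self.length_px < 20 or self.width_px < 8:
            raise ValueError("leaf too small to render")
        for ang in (self.secondary_vein_angle_lower, self.secondary_vein_angle_upper):
            if not 0.0 < ang < 90.0:
                raise ValueError("secondary vein angles must be in (0, 90) degrees")
        if not 0.0 <= self.damage_fraction <= 0.3:
            raise ValueError("damage_fraction must be in [0, 0.3]")
        if not -45.0 <= self.tilt_deg <= 45.0:
            raise ValueError("tilt_deg must be within +/-45 degrees")
        if self.lobe_count and not 0.0 < self.lobe_depth < 0.9:
            raise ValueError("lobe_depth must be in (0, 0.9) when lobed")

    def replace(self, **kwargs) -> "LeafSpec":
        return dataclasses.replace(self, **kwargs)


def half_width_profile(spec: LeafSpec, t: np.ndarray) -> np.ndarray:
    """Half-width (pixels) at normalized position t in [0, 1], base to tip."""
    t = np.clip(np.asarray(t, dtype=float), 0.0, 1.0)
    if spec.outline == "elliptic":
        base = np.sqrt(4.0 * t * (1.0 - t))
    elif spec.outline == "obovate":  # widest toward the tip
        base = (t**2.0 * (1.0 - t)) / (((2 / 3) ** 2) * (1 / 3))
    elif spec.outline == "cordate":  # widest toward the base
        base = (t * (1.0 - t) ** 2.0) / ((1 / 3) * ((2 / 3) ** 2))
    else:  # lobed: elliptic carrier with sinusoidal indentations
        base = np.sqrt(4.0 * t * (1.0 - t))
    if spec.outline == "lobed":
        lobes = max(spec.lobe_count, 2)
        base = base * (1.0 - spec.lobe_depth * np.sin(np.pi * lobes * t) ** 2)
    return 0.5 * spec.width_px * base


def midvein_shift(spec: LeafSpec, t: np.ndarray) -> np.ndarray:
    """Horizontal midvein displacement (pixels) at normalized position t."""
    c = spec.midvein_curvature
    t = np.asarray(t, dtype=float)
    return c[0] + c[1] * t + c[2] * t**2 + c[3] * t**3


def render_leaf(
    spec: LeafSpec, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]], tuple[int, int]]:
    """Render one leaf; returns (image, true_mask, true_midvein, petiole).

    The midvein pixel list runs from the petiole (base) to the tip.
    """
    rng = np.random.default_rng(seed)
    L = spec.length_px
    pad = 8
    max_shift = int(np.ceil(np.abs(midvein_shift(spec, np.linspace(0, 1, 64))).max()))
    half_w = int(np.ceil(spec.width_px / 2))
    H = L + 2 * pad
    W = 2 * (half_w + max_shift) + 2 * pad
    center0 = W // 2
    base_row = H - pad - 1
    tip_row = base_row - (L - 1)

    rows = np.arange(tip_row, base_row + 1)
    t = (base_row - rows) / (L - 1)
    centers = center0 + midvein_shift(spec, t)
    widths = np.maximum(half_width_profile(spec, t), 1.0)

    mask = np.zeros((H, W), dtype=bool)
    col_idx = np.arange(W)
    for r, c, w in zip(rows, centers, widths):
        if w <= 0:
            continue
        mask[r, (col_idx >= c - w) & (col_idx <= c + w)] = True
    # the midvein itself is always lamina, keeping the mask connected
    # from base to tip even where the profile tapers below one pixel
    mask[rows, np.round(centers).astype(int)] = True

    image = np.full((H, W), BG_LEVEL)
    image[mask] = LAMINA_LEVEL

    midvein = [
        (int(r), int(round(c)))
        for r, c in zip(rows[::-1], centers[::-1])  # base -> tip
    ]
    petiole = midvein[0]

    _draw_secondary_veins(image, mask, spec, rows, centers, widths)
    # midvein on top, 2 px wide
    for r, c in midvein:
        image[r, max(c - 1, 0): c + 1] = MIDVEIN_LEVEL

    if spec.damage_fraction > 0:
        mask, image = _apply_damage(mask, image, spec, rng)

    if spec.overlap is not None:
        mask, image = _apply_overlap(mask, image, spec, seed)

    if spec.tilt_deg != 0.0:
        image, mask, pts = _rotate_all(image, mask, [petiole] + midvein, spec.tilt_deg)
        petiole = pts[0]
        midvein = pts[1:]

    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    return image, mask, midvein, petiole


def _draw_secondary_veins(image, mask, spec, rows, centers, widths) -> None:
    base_row = rows[-1]
    L = spec.length_px
    H, W = image.shape
    for r_attach in range(int(rows[-1]) - spec.vein_spacing_px,
                          int(rows[0]) + spec.vein_spacing_px,
                          -spec.vein_spacing_px):
        t_attach = (base_row - r_attach) / (L - 1)
        if not 0.05 < t_attach < 0.95:
            continue
        beta = (
            spec.secondary_vein_angle_lower
            if t_attach < 0.5
            else spec.secondary_vein_angle_upper
        )
        rad = np.deg2rad(beta)
        c_attach = float(np.interp(r_attach, rows, centers))
        for side in (-1.0, 1.0):
            # march outward and upward at angle beta from the (local) midvein
            n_steps = int(2.5 * widths.max()) + 4
            rr = r_attach - np.cos(rad) * np.arange(n_steps)
            cc = c_attach + side * np.sin(rad) * np.arange(n_steps)
            ri = np.round(rr).astype(int)
            ci = np.round(cc).astype(int)
            ok = (ri >= 0) & (ri < H) & (ci >= 0) & (ci < W)
            ri, ci = ri[ok], ci[ok]
            inside = mask[ri, ci]
            stop = np.argmin(inside) if not inside.all() else len(ri)
            image[ri[:stop], ci[:stop]] = VEIN_LEVEL


def _apply_damage(mask, image, spec, rng):
    target = spec.damage_fraction * mask.sum()
    removed = 0
    out_mask = mask.copy()
    out_img = image.copy()
    for _ in range(200):
        if removed >= target:
            break
        rr, cc = np.nonzero(out_mask)
        if len(rr) == 0:
            break
        k = rng.integers(len(rr))
        radius = rng.uniform(2.0, max(3.0, 0.06 * spec.length_px))
        dd = draw_disk((rr[k], cc[k]), radius, shape=mask.shape)
        bite = np.zeros_like(mask)
        bite[dd] = True
        bite &= out_mask
        removed += bite.sum()
        out_mask[bite] = False
        out_img[bite] = BG_LEVEL
    # keep the lamina a single component
    labels, n = ndimage.label(out_mask)
    if n > 1:
        sizes = ndimage.sum_labels(out_mask, labels, np.arange(1, n + 1))
        keep = labels == (1 + int(np.argmax(sizes)))
        out_img[out_mask & ~keep] = BG_LEVEL
        out_mask = keep
    return out_mask, out_img


def _apply_overlap(mask, image, spec, seed):
    other = spec.replace(overlap=None, damage_fraction=0.0)
    img2, mask2, _, _ = render_leaf(other, seed=seed + 10_007)
    dr, dc = spec.overlap
    shifted = np.zeros_like(mask)
    H, W = mask.shape
    r0, r1 = max(0, dr), min(H, H + dr)
    c0, c1 = max(0, dc), min(W, W + dc)
    shifted[r0:r1, c0:c1] = mask2[r0 - dr: r1 - dr, c0 - dc: c1 - dc]
    img_shift = np.full_like(image, BG_LEVEL)
    img_shift[r0:r1, c0:c1] = img2[r0 - dr: r1 - dr, c0 - dc: c1 - dc]
    out_img = image.copy()
    out_img[shifted] = img_shift[shifted]  # second leaf occludes the first
    out_mask = mask & ~shifted
    return out_mask, out_img


def _rotate_all(
    image: np.ndarray,
    mask: np.ndarray,
    points: list[tuple[int, int]],
    angle_deg: float,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Rotate image, mask and ground-truth points about the canvas center."""
    H, W = mask.shape
    rad = np.deg2rad(angle_deg)
    R = np.array([[np.cos(rad), -np.sin(rad)], [np.sin(rad), np.cos(rad)]])
    center = np.array([(H - 1) / 2.0, (W - 1) / 2.0])
    corners = np.array([[0, 0], [0, W - 1], [H - 1, 0], [H - 1, W - 1]], float)
    rc = (corners - center) @ R.T
    lo = rc.min(0)
    H_out = int(np.ceil(rc[:, 0].max() - lo[0])) + 1
    W_out = int(np.ceil(rc[:, 1].max() - lo[1])) + 1
    out_r, out_c = np.meshgrid(np.arange(H_out), np.arange(W_out), indexing="ij")
    q = np.stack([out_r.ravel() + lo[0], out_c.ravel() + lo[1]], 1)
    src = q @ R + center
    coords = [src[:, 0].reshape(H_out, W_out), src[:, 1].reshape(H_out, W_out)]
    img_rot = ndimage.map_coordinates(image, coords, order=1, cval=BG_LEVEL, mode="constant")
    mask_rot = ndimage.map_coordinates(
        mask.astype(np.uint8), coords, order=0, cval=0, mode="constant"
    ).astype(bool)
    pts = (np.asarray(points, float) - center) @ R.T - lo
    pts_i = [(int(round(r)), int(round(c))) for r, c in pts]
    # keep ground-truth points on the rotated mask despite rounding
    pts_i = [_snap_to_mask(mask_rot, p) for p in pts_i]
    return img_rot, mask_rot, pts_i


def _snap_to_mask(mask: np.ndarray, p: tuple[int, int]) -> tuple[int, int]:
    r, c = p
    H, W = mask.shape
    for radius in range(4):
        for dr in range(-radius, radius + 1):
            for dc in range(-radius, radius + 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < H and 0 <= cc < W and mask[rr, cc]:
                    return rr, cc
    return min(max(r, 0), H - 1), min(max(c, 0), W - 1)


# ---------------------------------------------------------------------------
# bending (inverse family of the normalization warp)
# ---------------------------------------------------------------------------


def bend_midvein(
    image: np.ndarray, mask: np.ndarray, cubic: tuple[float, float, float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Shift every row horizontally by ``cubic(row)`` (rows measured from the top).

    This is the exact inverse warp family used by straightening: image
    resampling is bilinear, mask nearest-neighbor.  The canvas is widened
    so no pixel is lost; a shift larger than the image width is refused.
    """
    img = np.asarray(image, dtype=np.float64)
    grid = np.asarray(mask, dtype=bool)
    H, W = grid.shape
    rows = np.arange(H, dtype=float)
    shift = np.polynomial.polynomial.polyval(rows, np.asarray(cubic, dtype=float))
    if np.abs(shift).max() > W:
        raise ValueError("bend shift exceeds the image width")
    lo = int(np.floor(min(shift.min(), 0.0)))
    hi = int(np.ceil(max(shift.max(), 0.0)))
    W_out = W + hi - lo
    out_r, out_c = np.meshgrid(np.arange(H), np.arange(W_out), indexing="ij")
    src_c = out_c + lo - shift[:, None]
    coords = [out_r.astype(float), src_c]
    bg = float(np.median(img[~grid])) if (~grid).any() else 0.0
    bent_img = ndimage.map_coordinates(img, coords, order=1, cval=bg, mode="constant")
    bent_mask = ndimage.map_coordinates(
        grid.astype(np.uint8), coords, order=0, cval=0, mode="constant"
    ).astype(bool)
    return bent_img, bent_mask


# ---------------------------------------------------------------------------
# benchmark generation
# ---------------------------------------------------------------------------


@dataclass
class Benchmark:
    """A generated dataset: manifest + specs + look-alike structure."""

    manifest: Manifest
    specs: dict[str, LeafSpec]
    lookalike_pairs: list[tuple[str, str]] = field(default_factory=list)
    out_dir: Path | None = None


def _base_spec(i: int, rng: np.random.Generator) -> LeafSpec:
    """Deterministic, well-separated species parameters.

    Mixed-radix enumeration over (outline family, vein-angle group, aspect):
    any two indices differ in at least one trait whose spacing is several
    times the within-species jitter.
    """
    family = OUTLINE_FAMILIES[i % len(OUTLINE_FAMILIES)]
    a = (i // len(OUTLINE_FAMILIES)) % 4  # vein-angle group
    wide = (i // 16) % 2
    angle_lower = 28.0 + 16.0 * a
    angle_upper = float(np.clip(angle_lower + (12.0 if a % 2 else -12.0), 5, 85))
    return LeafSpec(
        species_name=f"species_{i:02d}",
        outline=family,
        length_px=150,
        width_px=82 if wide else 54,
        lobe_count=3 + (a % 2) if family == "lobed" else 0,
        lobe_depth=0.30 + 0.12 * (a // 2) if family == "lobed" else 0.0,
        secondary_vein_angle_lower=angle_lower,
        secondary_vein_angle_upper=angle_upper,
        vein_spacing_px=12 + 2 * (a % 2),
        noise_sd=0.02,
    )


def draw_species_specs(
    n_species: int, difficulty: str, rng: np.random.Generator
) -> tuple[dict[str, LeafSpec], list[tuple[str, str]]]:
    """Sample species-level specs; "hard" produces look-alike pairs."""
    specs: dict[str, LeafSpec] = {}
    pairs: list[tuple[str, str]] = []
    if difficulty == "easy":
        for i in range(n_species):
            spec = _base_spec(i, rng)
            specs[spec.species_name] = spec
    elif difficulty == "hard":
        i = 0
        base_idx = 0
        while i < n_species:
            base = _base_spec(base_idx, rng)
            a = base.replace(species_name=f"species_{i:02d}")
            specs[a.species_name] = a
            i += 1
            if i < n_species:
                # congeneric look-alike differing in a single trait family, so
                # no single feature set can separate every pair
                kind = base_idx % 3
                if kind == 0:  # vein-angle difference only (FS3 territory)
                    b = base.replace(
                        species_name=f"species_{i:02d}",
                        secondary_vein_angle_lower=float(
                            np.clip(base.secondary_vein_angle_lower + 9.0, 5, 85)
                        ),
                        secondary_vein_angle_upper=float(
                            np.clip(base.secondary_vein_angle_upper + 9.0, 5, 85)
                        ),
                    )
                elif kind == 1:  # outline difference only (FS1/FS2 territory)
                    b = base.replace(
                        species_name=f"species_{i:02d}",
                        width_px=int(round(base.width_px * 1.12)),
                        lobe_depth=min(base.lobe_depth + 0.08, 0.85)
                        if base.lobe_count
                        else 0.0,
                    )
                else:  # aspect-ratio difference only
                    b = base.replace(
                        species_name=f"species_{i:02d}",
                        length_px=int(round(base.length_px * 1.12)),
                    )
                specs[b.species_name] = b
                pairs.append((a.species_name, b.species_name))
                i += 1
            base_idx += 1
    else:
        raise ValueError(f"unknown difficulty {difficulty!r}")
    return specs, pairs


def jitter_spec(spec: LeafSpec, rng: np.random.Generator, difficulty: str) -> LeafSpec:
    """Within-species leaf-to-leaf variation, plus a random midvein bend."""
    bend_amp = rng.uniform(-0.13, 0.13) * spec.length_px
    bend = (0.0, 0.0, float(bend_amp), float(rng.uniform(-0.5, 0.5) * bend_amp))
    scale = rng.uniform(0.95, 1.05)
    jitter_deg = 2.0 if difficulty == "easy" else 3.0
    return spec.replace(
        tilt_deg=float(rng.uniform(-12.0, 12.0)),
        length_px=max(40, int(round(spec.length_px * scale))),
        width_px=max(16, int(round(spec.width_px * rng.uniform(0.96, 1.04)))),
        secondary_vein_angle_lower=float(
            np.clip(spec.secondary_vein_angle_lower + rng.normal(0, jitter_deg), 5, 85)
        ),
        secondary_vein_angle_upper=float(
            np.clip(spec.secondary_vein_angle_upper + rng.normal(0, jitter_deg), 5, 85)
        ),
        midvein_curvature=bend,
    )


def generate_benchmark(
    n_species: int,
    n_per_species: int,
    difficulty: str = "easy",
    seed: int = 0,
    out_dir: str | Path = "benchmark",
) -> Benchmark:
    """Render a full benchmark dataset to ``out_dir`` and return its manifest.

    Writes one PNG image + mask + midvein CSV per leaf and a manifest CSV.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if n_per_species < 2:
        logger.warning("n_per_species < 2: leave-one-out cannot score these classes")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    (out_dir / "midveins").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    specs, pairs = draw_species_specs(n_species, difficulty, rng)
    records = []
    for s_i, (name, spec) in enumerate(sorted(specs.items())):
        for k in range(n_per_species):
            leaf_seed = int(rng.integers(2**31))
            leaf = jitter_spec(spec, rng, difficulty)
            image, mask, midvein, petiole = render_leaf(leaf, seed=leaf_seed)
            stem = f"{name}_{k:02d}"
            img_path = out_dir / "images" / f"{stem}.png"
            mask_path = out_dir / "masks" / f"{stem}.png"
            write_image(image, img_path)
            write_mask(mask, mask_path)
            np.savetxt(
                out_dir / "midveins" / f"{stem}.csv",
                np.asarray(midvein, dtype=int),
                fmt="%d",
                delimiter=",",
                header="row,col",
                comments="",
            )
            records.append(
                LeafRecord(
                    image_path=img_path,
                    species=name,
                    mask_path=mask_path,
                    petiole=petiole,
                )
            )
    manifest = Manifest(records=records)
    write_manifest(manifest, out_dir / "manifest.csv")
    return Benchmark(manifest=manifest, specs=specs, lookalike_pairs=pairs, out_dir=out_dir)
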