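import numpy as np
import pytest
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

from herbleaf.features import (
    FS2_NAMES,
    FeatureError,
    FeatureVector,
    fourier_descriptors,
    fourier_descriptors_from_contour,
    mirror_histogram,
    orientation_histograms,
    outer_contour,
    shape_descriptors,
)
from herbleaf.line_operator import LineMap
from herbleaf.normalization import NormalizedLeaf
from herbleaf.segmentation import BinaryMask

from conftest import disk_mask


def ellipse_mask(a, b, rot=0.0, center=None, shape=(400, 400)):
    m = np.zeros(shape, bool)
    c = center or (shape[0] // 2, shape[1] // 2)
    rr, cc = draw_ellipse(c[0], c[1], a, b, shape=shape, rotation=rot)
    m[rr, cc] = True
    return BinaryMask(m)


def random_blob_mask(rng, shape=(360, 360), base_r=90):
    th = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    r = base_r * (
        1
        + 0.2
        * np.sum(
            [
                rng.uniform(-1, 1) * np.cos(k * th + rng.uniform(0, 2 * np.pi))
                for k in range(2, 6)
            ],
            axis=0,
        )
        / 4
    )
    r = np.maximum(r, 10)
    m = np.zeros(shape, bool)
    pr, pc = draw_polygon(shape[0] / 2 + r * np.sin(th), shape[1] / 2 + r * np.cos(th), shape=shape)
    m[pr, pc] = True
    return BinaryMask(m)


class TestFourierDescriptors:
    def test_default_count_is_twenty(self, config):
        assert config.n_fourier == 20
        assert len(fourier_descriptors(disk_mask(40), 20)) == 20

    def test_circle_descriptors_near_zero(self):
        d = fourier_descriptors(disk_mask(40), 20)
        assert np.all(d <= 0.02)

    def test_contour_level_invariance_exact(self, rng):
        mask = random_blob_mask(rng)
        contour = outer_contour(mask)
        d0 = fourier_descriptors_from_contour(contour, 20)
        # similarity transform: rotate 37 deg, scale x2, translate, roll start
        th = np.deg2rad(37.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = 2.0 * (contour @ R.T) + np.array([17.0, -5.0])
        moved = np.roll(moved, 61, axis=0)
        d1 = fourier_descriptors_from_contour(moved, 20)
        assert np.linalg.norm(d1 - d0) / np.linalg.norm(d0) <= 1e-3

    def test_raster_invariance_robustness(self):
        d0 = fourier_descriptors(ellipse_mask(80, 40), 20)
        d1 = fourier_descriptors(
            ellipse_mask(160, 80, rot=np.deg2rad(37.0), center=(190, 215), shape=(420, 430)),
            20,
        )
        assert np.linalg.norm(d1 - d0) / np.linalg.norm(d0) <= 0.05

    def test_ellipse_against_direct_dft_oracle(self):
        # independent oracle: analytically sampled ellipse contour,
        # direct O(N^2) Fourier summation (no FFT)
        a, b = 80.0, 40.0
        t_dense = np.linspace(0, 2 * np.pi, 20000, endpoint=False)
        pts = np.stack([a * np.sin(t_dense), b * np.cos(t_dense)], 1)
        seg = np.sqrt((np.diff(pts, axis=0) ** 2).sum(1))
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        total = arc[-1] + np.hypot(*(pts[0] - pts[-1]))
        targets = np.linspace(0, total, 256, endpoint=False)
        rows = np.interp(targets, arc, pts[:, 0])
        cols = np.interp(targets, arc, pts[:, 1])
        z = cols + 1j * rows
        N = len(z)
        n = np.arange(N)
        direct = {
            k: np.sum(z * np.exp(-2j * np.pi * k * n / N)) / N for k in (-1, 1)
        }
        oracle = np.abs(direct[-1]) / np.abs(direct[1])
        d = fourier_descriptors(ellipse_mask(int(a), int(b)), 20)
        # frequency -1 is the last entry of the negative block
        value = d[9]
        assert value == pytest.approx(oracle, rel=0.01)

    def test_multi_component_error(self):
        grid = np.zeros((30, 30), bool)
        grid[2:8, 2:8] = True
        grid[20:26, 20:26] = True
        with pytest.raises(FeatureError, match="component"):
            fourier_descriptors(BinaryMask(grid), 20)


class TestShapeDescriptors:
    def test_circle_closed_forms(self):
        d = dict(zip(FS2_NAMES, shape_descriptors(disk_mask(40))))
        assert 0.95 <= d["compactness"] <= 1.05
        assert 0.98 <= d["convexity"] <= 1.02
        assert d["solidity"] >= 0.98
        assert 1.0 <= d["dispersion"] <= 1.05

    def test_square_closed_forms(self):
        grid = np.zeros((60, 60), bool)
        grid[5:55, 5:55] = True
        d = dict(zip(FS2_NAMES, shape_descriptors(BinaryMask(grid))))
        assert d["rectangularity"] >= 0.98
        assert d["solidity"] >= 0.98
        assert d["slimness"] == pytest.approx(1.0)

    def test_l_shape_solidity(self):
        s = 120
        grid = np.zeros((s + 10, s + 10), bool)
        grid[5: 5 + s, 5: 5 + s] = True
        grid[5: 5 + s // 2, 5 + s // 2: 5 + s] = False  # remove one quadrant
        d = dict(zip(FS2_NAMES, shape_descriptors(BinaryMask(grid))))
        assert d["solidity"] == pytest.approx(6.0 / 7.0, abs=0.02)

    def test_triangle_max_thickness_at_base(self):
        # upward isoceles triangle: widest at the bottom (base)
        grid = np.zeros((110, 110), bool)
        pr, pc = draw_polygon([5, 105, 105], [55, 5, 105], shape=grid.shape)
        grid[pr, pc] = True
        d = dict(zip(FS2_NAMES, shape_descriptors(BinaryMask(grid))))
        assert d["max_thickness_position"] <= 0.05

    def test_all_finite(self, rng):
        d = shape_descriptors(random_blob_mask(rng))
        assert np.isfinite(d).all()
        assert len(d) == 9

    def test_zero_area_error(self):
        with pytest.raises((FeatureError, Exception)):
            shape_descriptors(BinaryMask(np.zeros((10, 10), bool)))


def _fixture_normleaf(shape=(100, 81), vein_col=40):
    grid = np.zeros(shape, bool)
    grid[5:95, 5:76] = True
    return NormalizedLeaf(
        image=np.zeros(shape),
        mask=BinaryMask(grid),
        vein_column=vein_col,
        base_row=94,
        tip_row=5,
    )


def _linemap_with(angles_by_quadrant, shape=(100, 81), vein_col=40, mid_row=50):
    """LineMap with constant orientation per quadrant and unit strength."""
    orientation = np.zeros(shape)
    strength = np.ones(shape)
    rr, cc = np.indices(shape)
    quads = {
        "ul": (rr < mid_row) & (cc < vein_col),
        "ur": (rr < mid_row) & (cc > vein_col),
        "ll": (rr >= mid_row) & (cc < vein_col),
        "lr": (rr >= mid_row) & (cc > vein_col),
    }
    for name, sel in quads.items():
        orientation[sel] = angles_by_quadrant[name]
    return LineMap(strength=strength, orientation=orientation, n_orientations=24)


class TestOrientationHistograms:
    def test_default_bins_24(self, config):
        assert config.n_hist_bins == 24

    def test_vertical_lines_peak_at_90(self):
        nl = _fixture_normleaf()
        lm = _linemap_with({"ul": 90.0, "ur": 90.0, "ll": 90.0, "lr": 90.0})
        fs3 = orientation_histograms(lm, nl, 24, margin_erosion=0)
        upper, lower = fs3[:24], fs3[24:]
        bin_90 = int(round(90 / 7.5))
        assert upper[bin_90] >= 0.9
        assert lower[bin_90] >= 0.9

    def test_known_angles_by_half(self):
        # lower-left 45 deg, upper-left 75 deg; right side carries the
        # mirrored angles so mirror-averaging maps them back
        lm = _linemap_with({"ll": 45.0, "ul": 75.0, "lr": 135.0, "ur": 105.0})
        nl = _fixture_normleaf()
        fs3 = orientation_histograms(lm, nl, 24, margin_erosion=0)
        upper, lower = fs3[:24], fs3[24:]
        assert np.argmax(lower) == int(round(45 / 7.5))
        assert np.argmax(upper) == int(round(75 / 7.5))

    def test_mirror_flip_invariance(self):
        nl = _fixture_normleaf()
        rng = np.random.default_rng(0)
        shape = nl.mask.grid.shape
        angles = rng.choice(np.arange(24) * 7.5, size=shape)
        strength = rng.random(shape)
        lm = LineMap(strength=strength, orientation=angles, n_orientations=24)
        fs3 = orientation_histograms(lm, nl, 24, margin_erosion=0)
        # mirrored leaf: flip arrays about the vein column, mirror angles
        flip_col = 2 * nl.vein_column
        W = shape[1]
        assert flip_col + 1 == W  # fixture symmetric about the vein column
        lm_m = LineMap(
            strength=strength[:, ::-1],
            orientation=(180.0 - angles[:, ::-1]) % 180.0,
            n_orientations=24,
        )
        nl_m = NormalizedLeaf(
            image=nl.image[:, ::-1],
            mask=BinaryMask(nl.mask.grid[:, ::-1]),
            vein_column=W - 1 - nl.vein_column,
            base_row=nl.base_row,
            tip_row=nl.tip_row,
        )
        fs3_m = orientation_histograms(lm_m, nl_m, 24, margin_erosion=0)
        assert np.allclose(fs3, fs3_m, atol=1e-9)

    def test_conservation_unnormalized(self):
        nl = _fixture_normleaf()
        rng = np.random.default_rng(3)
        shape = nl.mask.grid.shape
        lm = LineMap(
            strength=rng.normal(0, 1, shape),
            orientation=rng.choice(np.arange(24) * 7.5, size=shape),
            n_orientations=24,
        )
        fs3 = orientation_histograms(
            lm, nl, 24, normalize=False, margin_erosion=0,
            strength_quantile=0.0, vein_band=0,
        )
        w = np.maximum(lm.strength, 0.0)
        rr, cc = np.indices(shape)
        grid = nl.mask.grid
        mid = 0.5 * (nl.tip_row + nl.base_row)
        for half, sel_rows in (("upper", rr < mid), ("lower", rr >= mid)):
            left = grid & sel_rows & (cc < nl.vein_column)
            right = grid & sel_rows & (cc > nl.vein_column)
            expected = 0.5 * (w[left].sum() + w[right].sum())
            got = fs3[:24].sum() if half == "upper" else fs3[24:].sum()
            assert got == pytest.approx(expected, rel=1e-6)

    def test_mirror_histogram_mapping(self):
        h = np.arange(24.0)
        m = mirror_histogram(h)
        assert m[0] == h[0]
        for j in range(1, 24):
            assert m[j] == h[24 - j]

    def test_empty_half_warns_zero(self, caplog):
        nl = _fixture_normleaf()
        grid = nl.mask.grid.copy()
        grid[:50, :] = False  # empty the upper half
        nl2 = NormalizedLeaf(
            image=nl.image, mask=BinaryMask(grid), vein_column=nl.vein_column,
            base_row=nl.base_row, tip_row=nl.tip_row,
        )
        lm = _linemap_with({"ul": 0, "ur": 0, "ll": 45.0, "lr": 135.0})
        with caplog.at_level("WARNING", logger="herbleaf"):
            fs3 = orientation_histograms(lm, nl2, 24, margin_erosion=0)
        assert np.all(fs3[:24] == 0)
        assert fs3[24:].sum() == pytest.approx(1.0)


class TestExtractAll:
    def test_dimensionality_and_determinism(self, small_leaf, config):
        from herbleaf.pipeline import process_leaf

        _, v1 = process_leaf(
            small_leaf["image"], BinaryMask(small_leaf["mask"]), small_leaf["petiole"], config
        )
        _, v2 = process_leaf(
            small_leaf["image"], BinaryMask(small_leaf["mask"]), small_leaf["petiole"], config
        )
        assert len(v1) == 77
        assert len(v1.fs1) == 20 and len(v1.fs2) == 9 and len(v1.fs3) == 48
        for a, b in zip(v1.blocks.values(), v2.blocks.values()):
            assert np.array_equal(a, b)

    def test_block_selection(self):
        v = FeatureVector(np.ones(20), np.full(9, 2.0), np.full(48, 3.0))
        assert len(v.concat(("fs1", "fs3"))) == 68
        with pytest.raises(KeyError):
            v.concat(("fs1", "nope"))
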