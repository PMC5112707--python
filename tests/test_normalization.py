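import numpy as np
import pytest

from herbleaf.line_operator import line_response_multiscale
from herbleaf.normalization import (
    NormalizationError,
    default_petiole,
    detect_tip,
    fit_midvein_cubic,
    minimal_path,
    path_cost,
    rotation_to_vertical,
    straighten,
    trace_main_vein,
    MidveinPath,
)
from herbleaf.segmentation import BinaryMask
from herbleaf.pipeline import process_leaf

from conftest import mask_iou


def bellman_ford_cost(eps, grid, start, end):
    """Independent oracle: exhaustive relaxation to the shortest-path fixpoint."""
    H, W = eps.shape
    dist = np.full((H, W), np.inf)
    dist[start] = 0.0
    steps = [(dr, dc, np.hypot(dr, dc)) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
             if (dr, dc) != (0, 0)]
    for _ in range(H * W):
        changed = False
        for r in range(H):
            for c in range(W):
                if not grid[r, c] or not np.isfinite(dist[r, c]):
                    continue
                for dr, dc, step in steps:
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < H and 0 <= c2 < W and grid[r2, c2]:
                        cand = dist[r, c] + 0.5 * (eps[r, c] + eps[r2, c2]) * step
                        if cand < dist[r2, c2] - 1e-15:
                            dist[r2, c2] = cand
                            changed = True
        if not changed:
            break
    return dist[end]


def enumerate_simple_paths_cost(eps, grid, start, end):
    """Literal exhaustive DFS over all simple paths (tiny masks only)."""
    H, W = eps.shape
    best = [np.inf]
    steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]

    def dfs(pos, visited, cost):
        if cost >= best[0]:
            return
        if pos == end:
            best[0] = cost
            return
        r, c = pos
        for dr, dc in steps:
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < H and 0 <= c2 < W and grid[r2, c2] and (r2, c2) not in visited:
                step = np.hypot(dr, dc)
                dfs(
                    (r2, c2),
                    visited | {(r2, c2)},
                    cost + 0.5 * (eps[r, c] + eps[r2, c2]) * step,
                )

    dfs(start, {start}, 0.0)
    return best[0]


class TestDetectTip:
    def test_default_fraction_is_two_percent(self, config):
        assert config.tip_fraction == 0.02

    def test_vertical_ellipse(self):
        rr, cc = np.indices((81, 41))
        grid = ((rr - 40) / 38.0) ** 2 + ((cc - 20) / 15.0) ** 2 <= 1
        tip = detect_tip(BinaryMask(grid), petiole=(78, 20), tip_fraction=0.02)
        assert tip == (2, 20)

    def test_vertical_bar_projection_count(self):
        grid = np.zeros((104, 5), bool)
        grid[2:102, 2] = True  # 100-pixel bar
        tip = detect_tip(BinaryMask(grid), petiole=(101, 2), tip_fraction=0.02)
        assert tip == (2, 2)

    def test_petiole_outside_bbox_error(self):
        grid = np.zeros((10, 10), bool)
        grid[4:7, 4:7] = True
        with pytest.raises(NormalizationError, match="bounding box"):
            detect_tip(BinaryMask(grid), petiole=(0, 0), tip_fraction=0.02)

    def test_default_petiole_lowest_row_center(self):
        grid = np.zeros((10, 10), bool)
        grid[2:8, 3:6] = True
        assert default_petiole(BinaryMask(grid)) == (7, 4)


class TestMinimalPath:
    def test_single_column_bar(self):
        grid = np.zeros((20, 3), bool)
        grid[:, 1] = True
        eps = np.ones(grid.shape)
        path, cost = minimal_path(eps, grid, (19, 1), (0, 1))
        assert path == [(r, 1) for r in range(19, -1, -1)]
        assert cost == pytest.approx(19.0)

    @pytest.mark.parametrize("trial", range(10))
    def test_10x10_bellman_ford_oracle(self, trial):
        rng = np.random.default_rng(200 + trial)
        eps = rng.random((10, 10)) * 2
        grid = np.ones((10, 10), bool)
        path, cost = minimal_path(eps, grid, (9, 0), (0, 9))
        oracle = bellman_ford_cost(eps, grid, (9, 0), (0, 9))
        assert cost == pytest.approx(oracle, abs=1e-10)
        assert cost == pytest.approx(path_cost(eps, path), abs=1e-10)

    @pytest.mark.parametrize("trial", range(5))
    def test_tiny_mask_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(300 + trial)
        grid = rng.random((3, 4)) > 0.25
        grid[2, 0] = grid[0, 3] = True
        eps = rng.random((3, 4))
        try:
            path, cost = minimal_path(eps, grid, (2, 0), (0, 3))
        except NormalizationError:
            assert not np.isfinite(
                enumerate_simple_paths_cost(eps, grid, (2, 0), (0, 3))
            )
            return
        oracle = enumerate_simple_paths_cost(eps, grid, (2, 0), (0, 3))
        assert cost == pytest.approx(oracle, abs=1e-12)

    def test_disconnected_mask_error(self):
        grid = np.zeros((5, 5), bool)
        grid[0, 0] = grid[4, 4] = True
        with pytest.raises(NormalizationError, match="unreachable"):
            minimal_path(np.ones((5, 5)), grid, (4, 4), (0, 0))

    def test_path_is_8_connected_and_simple(self, rng):
        eps = rng.random((12, 12))
        grid = np.ones((12, 12), bool)
        path, _ = minimal_path(eps, grid, (11, 0), (0, 11))
        assert len(set(path)) == len(path)
        for (r0, c0), (r1, c1) in zip(path[:-1], path[1:]):
            assert max(abs(r1 - r0), abs(c1 - c0)) == 1


class TestTraceMainVein:
    def test_traced_vein_matches_ground_truth(self, bent_leaf):
        mask = BinaryMask(bent_leaf["mask"])
        lm = line_response_multiscale(bent_leaf["image"], 24, 15, 3)
        tip = detect_tip(mask, bent_leaf["petiole"], 0.02)
        mv = trace_main_vein(lm, mask, bent_leaf["petiole"], tip)
        true_cols = {r: c for r, c in bent_leaf["midvein"]}
        errs = [abs(c - true_cols[r]) for r, c in mv.pixels if r in true_cols]
        assert np.mean(errs) <= 2.0

    def test_cost_matches_path_cost(self, bent_leaf):
        from herbleaf.normalization import vein_cost_map

        mask = BinaryMask(bent_leaf["mask"])
        lm = line_response_multiscale(bent_leaf["image"], 24, 15, 3)
        tip = detect_tip(mask, bent_leaf["petiole"], 0.02)
        mv = trace_main_vein(lm, mask, bent_leaf["petiole"], tip)
        eps = vein_cost_map(lm, mask, bent_leaf["petiole"], tip)
        assert mv.cost == pytest.approx(path_cost(eps, mv.pixels), abs=1e-9)
        assert mv.pixels[0] == bent_leaf["petiole"]
        assert mv.pixels[-1] == tip


class TestFitCubic:
    def _path(self, pixels, petiole, tip):
        return MidveinPath(
            pixels=pixels,
            axis_g=(petiole, tip),
            delta_alpha=np.zeros((1, 1)),
            cost=0.0,
        )

    def test_vertical_path_constant(self):
        pixels = [(r, 7) for r in range(30, 4, -1)]
        path = self._path(pixels, (30, 7), (5, 7))
        coeffs = fit_midvein_cubic(path)
        assert coeffs[0] == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(coeffs[1:], 0.0, atol=1e-9)

    def test_known_cubic_recovered(self):
        # rotated frame == raw frame when g is vertical
        petiole, tip = (100, 50), (0, 50)
        a = np.array([0.0, 0.02, 3e-4, -2e-6])
        rows = np.arange(0, -101, -1, dtype=float)  # q-frame rows
        cols = np.polynomial.polynomial.polyval(rows, a)
        pixels = [(int(100 + r), 50 + c) for r, c in zip(rows, cols)]
        pixels = [(r, c) for r, c in pixels]
        path = MidveinPath(
            pixels=np.stack([100 + rows, 50 + cols], 1).tolist(),
            axis_g=(petiole, tip),
            delta_alpha=np.zeros((1, 1)),
            cost=0.0,
        )
        coeffs = fit_midvein_cubic(path)
        assert np.allclose(coeffs, a, atol=1e-6)

    def test_noisy_cubic_residual(self, rng):
        petiole, tip = (100, 50), (0, 50)
        a = np.array([0.0, 0.05, 1e-3, -8e-6])
        rows = np.arange(0, -101, -1, dtype=float)
        cols = np.polynomial.polynomial.polyval(rows, a) + rng.normal(0, 1, rows.size)
        path = MidveinPath(
            pixels=np.stack([100 + rows, 50 + cols], 1).tolist(),
            axis_g=(petiole, tip),
            delta_alpha=np.zeros((1, 1)),
            cost=0.0,
        )
        coeffs = fit_midvein_cubic(path)
        fitted = np.polynomial.polynomial.polyval(rows, coeffs)
        rms = np.sqrt(np.mean((fitted - cols) ** 2))
        assert rms <= 1.5

    def test_too_few_pixels_error(self):
        path = self._path([(10, 5), (9, 5), (8, 5)], (10, 5), (8, 5))
        with pytest.raises(NormalizationError):
            fit_midvein_cubic(path)


class TestStraighten:
    def test_already_straight_identity(self, small_leaf):
        mask = BinaryMask(small_leaf["mask"])
        petiole = small_leaf["petiole"]
        tip = small_leaf["midvein"][-1]
        cubic = np.zeros(4)
        out = straighten(small_leaf["image"], mask, petiole, tip, cubic)
        assert mask_iou(out.mask.grid, mask.grid) >= 0.995
        assert out.tip_row < out.base_row

    def test_bent_leaf_straightened_recovers_straight_shape(
        self, small_leaf, bent_leaf
    ):
        # same spec, same seed; one rendered straight, one bent
        norm, _ = process_leaf(
            bent_leaf["image"],
            BinaryMask(bent_leaf["mask"]),
            bent_leaf["petiole"],
            __import__("herbleaf.config", fromlist=["PipelineConfig"]).PipelineConfig(),
        )
        assert mask_iou(norm.mask.grid, small_leaf["mask"]) >= 0.95

    def test_area_near_conservation(self, bent_leaf, config):
        norm, _ = process_leaf(
            bent_leaf["image"], BinaryMask(bent_leaf["mask"]), bent_leaf["petiole"], config
        )
        a0 = bent_leaf["mask"].sum()
        assert abs(norm.mask.area - a0) / a0 <= 0.02

    def test_retrace_self_consistency(self, bent_leaf, config):
        norm, _ = process_leaf(
            bent_leaf["image"], BinaryMask(bent_leaf["mask"]), bent_leaf["petiole"], config
        )
        lm = line_response_multiscale(norm.image, 24, 15, 3)
        petiole = default_petiole(norm.mask)
        tip = detect_tip(norm.mask, petiole, 0.02)
        mv = trace_main_vein(lm, norm.mask, petiole, tip)
        cols = np.array([c for _, c in mv.pixels], dtype=float)
        rows = np.array([r for r, _ in mv.pixels])
        inner = (rows > norm.tip_row + 5) & (rows < norm.base_row - 5)
        assert np.abs(cols[inner] - norm.vein_column).max() <= 1.5

    def test_idempotence(self, bent_leaf, config):
        norm1, _ = process_leaf(
            bent_leaf["image"], BinaryMask(bent_leaf["mask"]), bent_leaf["petiole"], config
        )
        norm2, _ = process_leaf(norm1.image, norm1.mask, None, config)
        assert mask_iou(norm2.mask.grid, norm1.mask.grid) >= 0.99


class TestRotationFrame:
    def test_rotation_maps_tip_above_petiole(self):
        R = rotation_to_vertical((50, 10), (20, 40))
        g = np.array([20 - 50, 40 - 10], dtype=float)
        q = R @ g
        assert q[0] == pytest.approx(-np.hypot(*g))
        assert q[1] == pytest.approx(0.0, abs=1e-12)
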