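import numpy as np
import pytest

from herbleaf.config import PipelineConfig
from herbleaf.segmentation import BinaryMask
from herbleaf.synthetic import LeafSpec, render_leaf


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_leaf():
    """A small straight synthetic leaf with ground truth (deterministic)."""
    spec = LeafSpec(species_name="straight", length_px=120, width_px=60, noise_sd=0.01)
    image, mask, midvein, petiole = render_leaf(spec, seed=5)
    return {"spec": spec, "image": image, "mask": mask, "midvein": midvein, "petiole": petiole}


@pytest.fixture(scope="session")
def bent_leaf():
    """A bent synthetic leaf with ground truth (deterministic)."""
    spec = LeafSpec(
        species_name="bent",
        length_px=120,
        width_px=60,
        midvein_curvature=(0.0, 0.0, 12.0, -5.0),
        noise_sd=0.01,
    )
    image, mask, midvein, petiole = render_leaf(spec, seed=5)
    return {"spec": spec, "image": image, "mask": mask, "midvein": midvein, "petiole": petiole}


def disk_mask(radius: int, pad: int = 6) -> BinaryMask:
    n = 2 * (radius + pad) + 1
    c = n // 2
    rr, cc = np.indices((n, n))
    return BinaryMask((rr - c) ** 2 + (cc - c) ** 2 <= radius**2)


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """IoU after aligning the two masks by their bounding boxes."""
    def crop(m):
        rows, cols = np.nonzero(m)
        return m[rows.min(): rows.max() + 1, cols.min(): cols.max() + 1]

    ca, cb = crop(np.asarray(a, bool)), crop(np.asarray(b, bool))
    H = max(ca.shape[0], cb.shape[0])
    W = max(ca.shape[1], cb.shape[1])
    pa = np.zeros((H, W), bool)
    pb = np.zeros((H, W), bool)
    pa[: ca.shape[0], : ca.shape[1]] = ca
    pb[: cb.shape[0], : cb.shape[1]] = cb
    return float((pa & pb).sum() / (pa | pb).sum())
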