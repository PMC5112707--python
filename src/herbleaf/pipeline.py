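"""End-to-end orchestration: segment -> veinmap -> normalize -> features -> evaluate.

Per-leaf failures are recorded and skipped (herbarium material is messy);
only systemic configuration problems abort a batch.  Extracted feature
vectors are cached as small JSON files under the output directory, so a
resumed run produces outputs identical to a fresh one.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from herbleaf import classification, dataset_io
from herbleaf.config import PipelineConfig
from herbleaf.dataset_io import Manifest
from herbleaf.features import FeatureVector, extract_all
from herbleaf.line_operator import line_response_multiscale
from herbleaf.normalization import (
    NormalizedLeaf,
    default_petiole,
    detect_tip,
    fit_midvein_cubic,
    straighten,
    trace_main_vein,
)
from herbleaf.segmentation import BinaryMask, cleanup_mask, lazy_snap

logger = logging.getLogger("herbleaf")

DEFAULT_SUBSETS = (("fs1",), ("fs2",), ("fs3",), ("fs1", "fs2", "fs3"))


@dataclass
class LeafStatus:
    leaf_id: str
    ok: bool
    stage: str = "done"
    reason: str = ""


@dataclass
class RunReport:
    statuses: list[LeafStatus]
    accuracies: dict[str, float]
    confusion_path: str | None
    config: dict
    elapsed_s: float = 0.0
    features_path: str | None = None

    @property
    def n_ok(self) -> int:
        return sum(s.ok for s in self.statuses)

    def to_dict(self) -> dict:
        return {
            "statuses": [vars(s) for s in self.statuses],
            "accuracies": self.accuracies,
            "confusion_path": self.confusion_path,
            "features_path": self.features_path,
            "config": self.config,
            "elapsed_s": self.elapsed_s,
        }


def _to_gray(image: np.ndarray) -> np.ndarray:
    return image.mean(axis=2) if image.ndim == 3 else image


def process_leaf(
    image: np.ndarray,
    mask: BinaryMask,
    petiole: tuple[int, int] | None,
    config: PipelineConfig,
) -> tuple[NormalizedLeaf, FeatureVector]:
    """Normalize one segmented leaf and extract its feature vector.

    With ``config.normalize`` off, the leaf is used as-is (bounding-box
    base/tip, centroid vein column) — the ablation baseline.
    """
    gray = _to_gray(image)
    if petiole is None:
        petiole = default_petiole(mask)
    tip = detect_tip(mask, petiole, config.tip_fraction)
    if config.normalize:
        linemap = line_response_multiscale(
            gray, config.n_orientations, config.template_length, config.n_scales
        )
        path = trace_main_vein(linemap, mask, petiole, tip)
        cubic = fit_midvein_cubic(path)
        normleaf = straighten(gray, mask, petiole, tip, cubic)
        # nearest-neighbor resampling can shed isolated satellite pixels
        labels, n = ndimage.label(normleaf.mask.grid, structure=np.ones((3, 3), int))
        if n > 1:
            sizes = ndimage.sum_labels(normleaf.mask.grid, labels, np.arange(1, n + 1))
            normleaf.mask = BinaryMask(labels == 1 + int(np.argmax(sizes)))
    else:
        rows, cols = np.nonzero(mask.grid)
        normleaf = NormalizedLeaf(
            image=gray,
            mask=mask,
            vein_column=int(round(cols.mean())),
            base_row=int(rows.max()),
            tip_row=int(rows.min()),
        )
    return normleaf, extract_all(normleaf, config)


def _leaf_id(record) -> str:
    return Path(record.image_path).stem


def run_pipeline(
    manifest: Manifest,
    config: PipelineConfig,
    out_dir: str | Path,
    subsets=DEFAULT_SUBSETS,
    resume: bool = True,
) -> RunReport:
    """Run the full pipeline over a manifest and evaluate with leave-one-out."""
    t0 = time.time()
    out_dir = Path(out_dir)
    cache_dir = out_dir / "cache"
    cache_dir.mkdir(parents=True, exist_ok=True)
    config.log()
    config.save(out_dir / "config.yaml")

    statuses: list[LeafStatus] = []
    ids: list[str] = []
    species: list[str] = []
    vectors: list[FeatureVector] = []
    for record in manifest:
        leaf_id = _leaf_id(record)
        cache_file = cache_dir / f"{leaf_id}.json"
        try:
            if resume and cache_file.exists():
                data = json.loads(cache_file.read_text())
                vec = FeatureVector(**{k: np.asarray(v) for k, v in data.items()})
            else:
                vec = _process_record(record, config)
                cache_file.write_text(
                    json.dumps({k: v.tolist() for k, v in vec.blocks.items()})
                )
            ids.append(leaf_id)
            species.append(record.species)
            vectors.append(vec)
            statuses.append(LeafStatus(leaf_id, ok=True))
        except Exception as exc:  # per-leaf fault isolation
            logger.error("leaf %s failed: %s", leaf_id, exc)
            statuses.append(LeafStatus(leaf_id, ok=False, stage="pipeline", reason=str(exc)))

    features_path = out_dir / "features.csv"
    dataset_io.write_features(ids, species, vectors, features_path)

    accuracies: dict[str, float] = {}
    confusion_path = None
    if len(set(species)) >= 2 and len(species) >= 2:
        table = classification.evaluate_feature_subsets(
            vectors, species, subsets, C=config.svm_C
        )
        accuracies = dict(zip(table["subset"], table["accuracy"]))
        table.to_csv(out_dir / "subset_accuracies.csv", index=False)
        _, confusion = classification.loo_evaluate(vectors, species, C=config.svm_C)
        confusion_path = out_dir / "confusion.csv"
        dataset_io.write_confusion(confusion, confusion_path)
    else:
        logger.warning("fewer than 2 classes with features; skipping evaluation")

    report = RunReport(
        statuses=statuses,
        accuracies=accuracies,
        confusion_path=str(confusion_path) if confusion_path else None,
        features_path=str(features_path),
        config=config.to_dict(),
        elapsed_s=time.time() - t0,
    )
    (out_dir / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    return report


def _process_record(record, config: PipelineConfig) -> FeatureVector:
    image = dataset_io.read_image(record.image_path)
    if record.mask_path is not None:
        mask = BinaryMask(dataset_io.read_mask(record.mask_path))
    elif record.scribble_path is not None:
        scribbles = dataset_io.read_scribbles(record.scribble_path)
        mask = cleanup_mask(lazy_snap(image, scribbles, config.seg_K, config.seg_lambda))
    else:
        raise RuntimeError("record has neither mask nor scribbles")
    _, vec = process_leaf(image, mask, record.petiole, config)
    return vec
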