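"""Reading and writing of on-disk artifacts.

Covers dataset manifests (CSV), images, binary masks and scribble rasters
(PNG), feature tables (CSV) and confusion matrices (CSV + heat-map).

Conventions used throughout the package:

* pixel coordinates are ``(row, col)``, 0-based, origin at the top left;
* masks are boolean arrays, written as 0/255 single-channel PNG;
* scribbles are single-channel PNG with 0 = background scribble,
  255 = foreground scribble, anything else = unlabeled;
* manifests are UTF-8 comma-separated CSV with a header.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger("herbleaf")

#: scribble raster codes
SCRIBBLE_BG = 0
SCRIBBLE_FG = 255
SCRIBBLE_NONE = 128


class ManifestError(ValueError):
    """Fatal problem with a manifest file."""


@dataclass
class LeafRecord:
    """One dataset entry: an image, its species label, and optional extras."""

    image_path: Path
    species: str
    mask_path: Path | None = None
    scribble_path: Path | None = None
    petiole: tuple[int, int] | None = None  # (row, col)
    split_tag: str = ""

    def __post_init__(self) -> None:
        self.image_path = Path(self.image_path)
        if self.mask_path is not None:
            self.mask_path = Path(self.mask_path)
        if self.scribble_path is not None:
            self.scribble_path = Path(self.scribble_path)
        if not self.species:
            raise ValueError("species label must be non-empty")
        if self.petiole is not None:
            self.petiole = (int(self.petiole[0]), int(self.petiole[1]))


@dataclass
class Manifest:
    """Ordered collection of :class:`LeafRecord` with per-species bookkeeping."""

    records: list[LeafRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        # deterministic ordering: species, then path
        self.records = sorted(
            self.records, key=lambda r: (r.species, str(r.image_path))
        )

    @property
    def n_species(self) -> int:
        return len({r.species for r in self.records})

    @property
    def n_per_species(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            counts[rec.species] = counts.get(rec.species, 0) + 1
        return counts

    @property
    def species_labels(self) -> list[str]:
        return sorted({r.species for r in self.records})

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


_REQUIRED_COLUMNS = ("image", "species")
_OPTIONAL_COLUMNS = ("mask", "scribbles", "petiole_row", "petiole_col", "split")


def read_manifest(path: str | Path, check_paths: bool = True) -> Manifest:
    """Parse a manifest CSV into a :class:`Manifest`.

    Required columns: ``image``, ``species``.  Optional: ``mask``,
    ``scribbles``, ``petiole_row``, ``petiole_col``, ``split``.  Relative
    paths are resolved against the manifest's directory.  Rows whose image
    does not exist are collected and reported as record-level errors (the
    manifest still loads); a missing file or column is fatal.
    """
    path = Path(path)
    if not path.is_file():
        raise ManifestError(f"manifest not found: {path}")
    base = path.parent
    records: list[LeafRecord] = []
    bad_rows: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ManifestError(f"{path}: empty file, header required")
        missing = [c for c in _REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ManifestError(f"{path}: missing required column(s) {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(_parse_row(row, base, check_paths))
            except ValueError as exc:
                bad_rows.append(f"line {lineno}: {exc}")
    if bad_rows:
        for msg in bad_rows:
            logger.error("manifest %s: %s", path, msg)
        raise ManifestError(
            f"{path}: {len(bad_rows)} malformed record(s): " + "; ".join(bad_rows)
        )
    if not records:
        logger.warning("manifest %s contains no records", path)
    return Manifest(records=records)


def _parse_row(row: dict, base: Path, check_paths: bool) -> LeafRecord:
    image = _resolve(row["image"], base)
    if check_paths and not image.is_file():
        raise ValueError(f"image does not exist: {image}")
    petiole = None
    pr, pc = row.get("petiole_row", ""), row.get("petiole_col", "")
    if (pr or "").strip() or (pc or "").strip():
        try:
            petiole = (int(pr), int(pc))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"bad petiole coordinates {pr!r},{pc!r}") from exc
    return LeafRecord(
        image_path=image,
        species=(row["species"] or "").strip(),
        mask_path=_resolve(row.get("mask"), base),
        scribble_path=_resolve(row.get("scribbles"), base),
        petiole=petiole,
        split_tag=(row.get("split") or "").strip(),
    )


def _resolve(value: str | None, base: Path) -> Path | None:
    if value is None or not value.strip():
        return None
    p = Path(value.strip())
    return p if p.is_absolute() else base / p


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    """Write a manifest CSV (paths relativized to the output directory when possible)."""
    path = Path(path)
    base = path.parent.resolve()

    def rel(p: Path | None) -> str:
        if p is None:
            return ""
        try:
            return str(Path(p).resolve().relative_to(base))
        except ValueError:
            return str(p)

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(_REQUIRED_COLUMNS) + list(_OPTIONAL_COLUMNS))
        for rec in manifest.records:
            pr = "" if rec.petiole is None else rec.petiole[0]
            pc = "" if rec.petiole is None else rec.petiole[1]
            writer.writerow(
                [
                    rel(rec.image_path),
                    rec.species,
                    rel(rec.mask_path),
                    rel(rec.scribble_path),
                    pr,
                    pc,
                    rec.split_tag,
                ]
            )


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------


def read_image(path: str | Path) -> np.ndarray:
    """Load an image as float64 in [0, 1]; grayscale 2-D or RGB 3-channel."""
    with Image.open(path) as img:
        if img.mode in ("I;16", "I"):
            arr = np.asarray(img, dtype=np.float64) / 65535.0
        elif img.mode in ("L", "RGB"):
            arr = np.asarray(img, dtype=np.float64) / 255.0
        else:
            img = img.convert("RGB")
            arr = np.asarray(img, dtype=np.float64) / 255.0
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return arr


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a float image in [0, 1] (2-D or RGB) as 8-bit PNG/TIFF/JPEG."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    Image.fromarray((arr * 255.0 + 0.5).astype(np.uint8)).save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Load a 0/255 mask PNG as a boolean array."""
    with Image.open(path) as img:
        arr = np.asarray(img.convert("L"))
    return arr >= 128


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8)).save(path)


def read_scribbles(path: str | Path) -> np.ndarray:
    """Load a scribble PNG as uint8 (0 = bg, 255 = fg, other = unlabeled)."""
    with Image.open(path) as img:
        return np.asarray(img.convert("L")).copy()


def write_scribbles(scribbles: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(scribbles, dtype=np.uint8)).save(path)


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------


def feature_columns(n_fourier: int = 20, n_fs2: int = 9, n_fs3: int = 48) -> list[str]:
    return (
        [f"fs1_{i:02d}" for i in range(n_fourier)]
        + [f"fs2_{i:02d}" for i in range(n_fs2)]
        + [f"fs3_{i:02d}" for i in range(n_fs3)]
    )


def write_features(
    ids: Sequence[str],
    species: Sequence[str],
    vectors: Iterable,
    path: str | Path,
) -> None:
    """Write feature vectors to CSV with columns id, species, fs1_*, fs2_*, fs3_*."""
    rows = []
    for vec in vectors:
        rows.append(np.concatenate([vec.fs1, vec.fs2, vec.fs3]))
    mat = np.asarray(rows, dtype=np.float64)
    vec0 = None if not rows else mat.shape[1]
    cols = feature_columns() if vec0 in (None, 77) else [f"f_{i:03d}" for i in range(vec0)]
    df = pd.DataFrame(mat, columns=cols)
    df.insert(0, "species", list(species))
    df.insert(0, "id", list(ids))
    df.to_csv(path, index=False, float_format="%.12g")


def read_features(path: str | Path) -> tuple[list[str], list[str], np.ndarray, list[str]]:
    """Read a feature CSV; returns (ids, species, matrix, feature column names)."""
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c not in ("id", "species")]
    return (
        df["id"].astype(str).tolist(),
        df["species"].astype(str).tolist(),
        df[cols].to_numpy(dtype=np.float64),
        cols,
    )


# ---------------------------------------------------------------------------
# confusion matrices
# ---------------------------------------------------------------------------


def write_confusion(matrix, path: str | Path, heatmap: bool = True) -> None:
    """Write a confusion matrix as CSV (rows = true, cols = predicted), plus a heat-map.

    ``matrix`` must expose ``counts`` (square integer array) and ``labels``.
    The heat-map PNG is written next to the CSV with suffix ``.png``.
    """
    counts = np.asarray(matrix.counts)
    labels = list(matrix.labels)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError("confusion matrix must be square")
    if counts.shape[0] != len(labels):
        raise ValueError("label count does not match matrix size")
    zero_rows = [labels[i] for i in np.flatnonzero(counts.sum(axis=1) == 0)]
    for lab in zero_rows:
        logger.warning("confusion matrix: class %r has no samples", lab)
    df = pd.DataFrame(counts, index=labels, columns=labels)
    df.index.name = "true"
    df.to_csv(path)
    if heatmap:
        _render_heatmap(counts, labels, Path(path).with_suffix(".png"))


def _render_heatmap(counts: np.ndarray, labels: list[str], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    row_sums = counts.sum(axis=1, keepdims=True)
    frac = np.divide(counts, np.maximum(row_sums, 1), dtype=float)
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * len(labels)),) * 2)
    im = ax.imshow(frac, cmap="viridis", vmin=0, vmax=1)
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=6)
    ax.set_yticks(range(len(labels)), labels, fontsize=6)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.colorbar(im, ax=ax, label="fraction of true class")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
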