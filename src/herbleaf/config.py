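"""Central pipeline configuration.

All tunables of the pipeline live in one dataclass so that every run can
log the fully resolved configuration.  Defaults follow the published
setup where one is stated (24 orientations, template length 15, three
scales, 2% tip fraction, 20 Fourier descriptors, 24 histogram bins);
everything else is an artifact decision exposed here.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

logger = logging.getLogger("herbleaf")


@dataclass
class PipelineConfig:
    """Resolved configuration for a full pipeline run."""

    # line operator
    n_orientations: int = 24
    template_length: int = 15
    n_scales: int = 3
    # normalization
    tip_fraction: float = 0.02
    # features
    n_fourier: int = 20
    n_hist_bins: int = 24
    normalize_histograms: bool = True
    fs3_strength_quantile: float = 0.75  # accumulate only strengths above this in-mask quantile
    # classifier
    svm_C: float = 1.0
    # segmentation
    seg_K: int = 8
    seg_lambda: float = 10.0
    # misc
    seed: int = 0
    normalize: bool = True  # apply midvein straightening before features

    def __post_init__(self) -> None:
        if self.n_orientations < 2:
            raise ValueError("n_orientations must be >= 2")
        if self.template_length < 3 or self.template_length % 2 == 0:
            raise ValueError("template_length must be odd and >= 3")
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")
        if not 0.0 < self.tip_fraction < 0.5:
            raise ValueError("tip_fraction must be in (0, 0.5)")
        if self.n_fourier < 2 or self.n_fourier % 2 != 0:
            raise ValueError("n_fourier must be even and >= 2")
        if self.svm_C <= 0:
            raise ValueError("svm_C must be positive")
        if self.seg_K < 1:
            raise ValueError("seg_K must be >= 1")
        if self.seg_lambda < 0:
            raise ValueError("seg_lambda must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def log(self) -> None:
        """Echo the resolved config into the log (auditability)."""
        for key, value in sorted(self.to_dict().items()):
            logger.info("config %s = %r", key, value)
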