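"""Raster and tabular I/O plus pipeline configuration.

Conventions used everywhere in the package: rasters are row-major numpy
arrays, 0-based, origin at the top-left; images are floats in [0, 1]
(integer inputs are normalized by their dtype maximum, 16-bit TIFFs by
the actual maximum representable value); masks round-trip losslessly
through 8-bit PNG.

Grade labels CSV schema: ``filename,grade`` with grade one of the five
gradable levels or ``ungradable``; ungradable rows are read and then
excluded with a logged count, mirroring clinical grading practice where
images of insufficient quality are dropped from analysis.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .attention import AttentionConfig
from .segnet import SegNetConfig
from .synthetic import GRADES

__all__ = [
    "PipelineConfig", "read_image", "write_image", "write_mask", "read_mask",
    "read_labels_csv", "write_labels_csv", "load_config", "dump_config",
]

logger = logging.getLogger("funduskit")

UNGRADABLE = "ungradable"
_VALID_LABELS = set(GRADES) | {UNGRADABLE}


def read_image(path) -> np.ndarray:
    """Read PNG/JPEG/TIFF into a float array in [0, 1]."""
    arr = iio.imread(path)
    if arr.dtype == np.uint8:
        out = arr.astype(float) / 255.0
    elif arr.dtype == np.uint16:
        out = arr.astype(float) / 65535.0
    elif np.issubdtype(arr.dtype, np.integer):
        out = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        out = np.clip(arr.astype(float), 0.0, 1.0)
    if out.ndim == 3 and out.shape[2] == 4:  # drop alpha
        out = out[..., :3]
    return out


def write_image(path, image: np.ndarray) -> None:
    """Write a [0, 1] raster as 8-bit PNG/TIFF."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(path, np.round(arr * 255).astype(np.uint8))


def write_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit PNG (0/255)."""
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask(path) -> np.ndarray:
    """Read a mask PNG back to boolean (any non-zero pixel is True)."""
    return iio.imread(path) > 0


def read_labels_csv(path, keep_ungradable: bool = False) -> pd.DataFrame:
    """Read a ``filename,grade`` CSV, validating and filtering grades.

    A grade outside the six admissible values raises ``ValueError``.
    Ungradable rows are excluded (with a logged count) unless
    ``keep_ungradable`` is set.
    """
    df = pd.read_csv(path)
    required = {"filename", "grade"}
    if not required.issubset(df.columns):
        raise ValueError(f"labels CSV must have columns {sorted(required)}")
    bad = set(df["grade"]) - _VALID_LABELS
    if bad:
        raise ValueError(f"unknown grade values {sorted(bad)}")
    n_un = int((df["grade"] == UNGRADABLE).sum())
    if n_un and not keep_ungradable:
        logger.info("excluding %d ungradable image(s)", n_un)
        df = df[df["grade"] != UNGRADABLE].reset_index(drop=True)
    return df


def write_labels_csv(path, rows: List[Tuple[str, str]]) -> None:
    pd.DataFrame(rows, columns=["filename", "grade"]).to_csv(path, index=False)


# ----------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; round-trips through YAML."""

    input_dir: str = "."
    output_dir: str = "out"
    labels_csv: Optional[str] = None
    seed: int = 0
    enhancement_lam: float = 0.2
    segmentation: SegNetConfig = field(default_factory=SegNetConfig)
    classifier: str = "improved_svm"     # improved_svm | improved_knn | svm:<kind> | knn:<kind>
    cv_folds: int = 10
    checkpoint: Optional[str] = None

    def to_dict(self) -> Dict:
        d = asdict(self)
        d["segmentation"]["attention"]["pyramid_levels"] = list(
            d["segmentation"]["attention"]["pyramid_levels"])
        return d

    @classmethod
    def from_dict(cls, d: Dict) -> "PipelineConfig":
        d = dict(d)
        seg = d.pop("segmentation", None)
        if seg is not None:
            att = seg.pop("attention", None)
            if att is not None:
                att["pyramid_levels"] = tuple(att["pyramid_levels"])
                seg["attention"] = AttentionConfig(**att)
            d["segmentation"] = SegNetConfig(**seg)
        return cls(**d)


def dump_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def load_config(path) -> PipelineConfig:
    return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()))
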