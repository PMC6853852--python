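"""End-to-end pipeline, configuration and result file I/O.

The full pipeline is crop -> FHH enhancement -> polarity graphs ->
sequential boundary extraction, with boundary rows reported in original
(pre-crop) image coordinates, 0-based, row 0 at the top. Boundary tables
round-trip through CSV; an RGB overlay PNG is available for visual QC.
"""

from __future__ import annotations

import dataclasses
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import SchemaError
from .fhh import FhhConfig, enhance
from .graph import GraphConfig
from .image import BScanImage, crop_top
from .segment import (
    BOUNDARY_LABELS,
    Boundary,
    SegmentConfig,
    SegmentationResult,
    segment_all,
)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "write_boundaries",
    "read_boundaries",
    "write_overlay",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of a segmentation run.

    crop_fraction is the fraction of the image height removed from the top
    before any processing, to discard the low-signal vitreous region
    (default 15%). The single seed drives every random component (only the
    phantom generator uses randomness; segmentation itself is
    deterministic).
    """

    fhh: FhhConfig = field(default_factory=FhhConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    crop_fraction: float = 0.15
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        fhh_kw = raw.get("fhh", {})
        graph_kw = raw.get("graph", {})
        seg_kw = raw.get("segment", {})
        return cls(
            fhh=FhhConfig(**fhh_kw),
            segment=SegmentConfig(graph=GraphConfig(**graph_kw), **seg_kw),
            crop_fraction=raw.get("crop_fraction", 0.15),
            seed=raw.get("seed", 0),
        )

    def to_toml(self, path: str | Path) -> None:
        """Write a snapshot of the effective configuration (provenance)."""
        lines = [
            f"crop_fraction = {self.crop_fraction}",
            f"seed = {self.seed}",
            "",
            "[fhh]",
        ]
        for f in dataclasses.fields(self.fhh):
            val = getattr(self.fhh, f.name)
            if val is not None:
                lines.append(f"{f.name} = {val}")
        lines += ["", "[graph]"]
        for f in dataclasses.fields(self.segment.graph):
            lines.append(f"{f.name} = {getattr(self.segment.graph, f.name)}")
        lines += ["", "[segment]"]
        lines.append(f"margin = {self.segment.margin}")
        lines.append(f"rpe_below_isos = {str(self.segment.rpe_below_isos).lower()}")
        Path(path).write_text("\n".join(lines) + "\n")


def run_pipeline(
    image: BScanImage, config: PipelineConfig | None = None
) -> tuple[SegmentationResult, dict]:
    """Crop, enhance and segment one B-scan.

    Returns the segmentation in original (pre-crop) coordinates plus an
    info dictionary with the applied fuzzifier and per-stage path costs.
    """
    config = config or PipelineConfig()
    cropped = crop_top(image, config.crop_fraction)
    enhanced, beta = enhance(cropped, config.fhh)
    result = segment_all(enhanced, config.segment)
    result = result.in_original_frame()
    info = {
        "beta": beta,
        "crop_rows": cropped.crop_offset - image.crop_offset,
        "path_costs": dict(result.path_costs),
        "ordering_ok": result.ordering_ok,
    }
    logger.info(
        "pipeline: beta=%.3f cropped=%d rows ordering_ok=%s",
        beta, info["crop_rows"], result.ordering_ok,
    )
    return result, info


def write_boundaries(
    result: SegmentationResult | dict[str, Boundary], path: str | Path
) -> None:
    """Boundary table as CSV: one row per column, 8 labeled row columns."""
    boundaries = result.boundaries if isinstance(result, SegmentationResult) else result
    width = len(next(iter(boundaries.values())).rows)
    data = {"column": np.arange(width)}
    for lb in BOUNDARY_LABELS:
        data[lb] = boundaries[lb].rows
    pd.DataFrame(data).to_csv(path, index=False)


def read_boundaries(path: str | Path) -> dict[str, Boundary]:
    """Read a boundary CSV, validating that all 8 labels are present."""
    frame = pd.read_csv(path)
    missing = [lb for lb in BOUNDARY_LABELS if lb not in frame.columns]
    if missing:
        raise SchemaError(
            f"boundary CSV {path} is missing column(s): {', '.join(missing)}"
        )
    return {
        lb: Boundary(lb, frame[lb].to_numpy(dtype=np.int64)) for lb in BOUNDARY_LABELS
    }


#: Distinct overlay colors, one per boundary (top to bottom).
_OVERLAY_COLORS = (
    (228, 26, 28),
    (55, 126, 184),
    (77, 175, 74),
    (152, 78, 163),
    (255, 127, 0),
    (255, 255, 51),
    (166, 86, 40),
    (247, 129, 191),
)


def write_overlay(
    image: BScanImage,
    result: SegmentationResult | dict[str, Boundary],
    path: str | Path,
) -> None:
    """RGB PNG of the B-scan with the 8 boundaries drawn in distinct colors."""
    boundaries = result.boundaries if isinstance(result, SegmentationResult) else result
    grey = np.clip(image.pixels / (image.max_grey - 1) * 255, 0, 255).astype(np.uint8)
    rgb = np.stack([grey] * 3, axis=-1)
    cols = np.arange(image.width)
    for color, lb in zip(_OVERLAY_COLORS, BOUNDARY_LABELS):
        rows = np.clip(boundaries[lb].rows, 0, image.height - 1)
        rgb[rows, cols] = color
    iio.imwrite(Path(path), rgb)
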