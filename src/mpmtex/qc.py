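"""Tile quality control: discard FoVs with borders, holes or saturation.

Tiles lying on a tissue border, containing large holes, or showing
detector saturation carry no usable texture signal and are removed before
feature extraction.  The rules are numeric reconstructions of a visual
curation step and therefore configurable:

* a pixel is *foreground* when its combined CARS + TPEF intensity exceeds
  a fraction of the combined intensity range (SHG is excluded on purpose:
  it is legitimately sparse in normal liver);
* *saturation*: fraction of pixels with any channel at the maximum
  representable value above ``max_saturated_fraction``;
* *low coverage* (tissue border): foreground coverage below
  ``min_coverage``;
* *hole*: largest 4-connected background component above
  ``max_hole_fraction`` of the tile area.

Reasons are evaluated in the order saturation -> low_coverage -> hole and
the first failure is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import FovImage, SampleRecord, max_representable

#: 4-connectivity structuring element for hole labelling.
_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

REASONS = ("ok", "low_coverage", "hole", "saturation")


@dataclass(frozen=True)
class QcThresholds:
    """Numeric tile-discard rules (all fractions in [0, 1])."""

    foreground_intensity_fraction: float = 0.05
    min_coverage: float = 0.90
    max_hole_fraction: float = 0.05
    max_saturated_fraction: float = 0.01

    def __post_init__(self):
        for name in (
            "foreground_intensity_fraction",
            "min_coverage",
            "max_hole_fraction",
            "max_saturated_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class QcStatus:
    """Outcome of tile QC; ``keep`` iff ``reason == 'ok'``."""

    keep: bool
    reason: str

    def __post_init__(self):
        if self.reason not in REASONS:
            raise ValueError(f"unknown QC reason {self.reason!r}")
        if self.keep != (self.reason == "ok"):
            raise ValueError("keep flag inconsistent with reason")


def _saturated_mask(fov: FovImage) -> np.ndarray:
    mask = np.zeros(fov.shape, dtype=bool)
    for arr in fov.channels().values():
        ceiling = max_representable(arr)
        if ceiling is None:
            ceiling = 1.0  # float rasters assumed normalized
        mask |= np.asarray(arr) >= ceiling
    return mask


def _foreground_mask(fov: FovImage, thresholds: QcThresholds) -> np.ndarray:
    combined = fov.cars.astype(np.float64) + fov.tpef.astype(np.float64)
    caps = [max_representable(fov.cars), max_representable(fov.tpef)]
    if None in caps:
        rng = float(combined.max())
    else:
        rng = float(sum(caps))
    return combined > thresholds.foreground_intensity_fraction * rng


def assess_fov(fov: FovImage, thresholds: QcThresholds = QcThresholds()) -> QcStatus:
    """Deterministic QC verdict for one FoV (first failing rule reported)."""
    sat_frac = _saturated_mask(fov).mean()
    if sat_frac > thresholds.max_saturated_fraction:
        return QcStatus(False, "saturation")
    fg = _foreground_mask(fov, thresholds)
    coverage = fg.mean()
    if coverage < thresholds.min_coverage:
        return QcStatus(False, "low_coverage")
    background = ~fg
    if background.any():
        labels, n = ndimage.label(background, structure=_STRUCTURE_4)
        if n:
            largest = np.bincount(labels.ravel())[1:].max()
            if largest / background.size > thresholds.max_hole_fraction:
                return QcStatus(False, "hole")
    return QcStatus(True, "ok")


def filter_sample(
    sample: SampleRecord, thresholds: QcThresholds = QcThresholds()
) -> tuple[SampleRecord, pd.DataFrame]:
    """Split a sample into kept FoVs and a discard table.

    The kept sample preserves grid positions; the discard table
    (fov_id, tile_row, tile_col, reason) feeds the dark-gray slots of the
    posterior-probability maps.  Filtering is idempotent.
    """
    kept, rows = [], []
    for fov in sample:
        status = assess_fov(fov, thresholds)
        if status.keep:
            kept.append(fov)
        else:
            rows.append(
                {
                    "fov_id": fov.fov_id,
                    "tile_row": fov.tile_row,
                    "tile_col": fov.tile_col,
                    "reason": status.reason,
                }
            )
    filtered = SampleRecord(
        patient_id=sample.patient_id,
        sample_id=sample.sample_id,
        tissue_label=sample.tissue_label,
        fovs=kept,
        grid_shape=sample.grid_shape,
    )
    table = pd.DataFrame(rows, columns=["fov_id", "tile_row", "tile_col", "reason"])
    return filtered, table
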