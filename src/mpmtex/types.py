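"""Core in-memory containers for multiphoton tile data.

A field of view (FoV) is one acquired tile: three co-registered
single-channel rasters — CARS (lipid contrast), TPEF (endogenous
fluorescence) and SHG (fibrillar collagen) — plus its position on the
acquisition tile grid.  A sample is one tissue block of one patient,
imaged as a grid of FoVs and carrying a single tissue label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

#: Fixed channel order used everywhere (storage, features, composites).
CHANNELS = ("cars", "tpef", "shg")

#: Default FoV geometry: 152 rows x 302 columns at 1 um/pixel.
DEFAULT_FOV_SHAPE = (152, 302)

TISSUE_LABELS = ("normal", "tumor")


def max_representable(raster: np.ndarray) -> Optional[int]:
    """Maximum representable intensity of a raster, or None for floats.

    Integer rasters saturate at the dtype maximum (65535 for the 16-bit
    storage format); float rasters have no hard ceiling.
    """
    if np.issubdtype(raster.dtype, np.integer):
        return int(np.iinfo(raster.dtype).max)
    return None


@dataclass
class FovImage:
    """One field of view: three co-registered channel rasters on a tile grid.

    Invariants (checked by :meth:`validate`): all three rasters share one
    shape, intensities are finite and non-negative, grid indices are
    non-negative.
    """

    cars: np.ndarray
    tpef: np.ndarray
    shg: np.ndarray
    tile_row: int
    tile_col: int
    fov_id: str

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.cars.shape)

    def channels(self) -> dict[str, np.ndarray]:
        return {"cars": self.cars, "tpef": self.tpef, "shg": self.shg}

    def validate(self) -> "FovImage":
        shapes = {name: arr.shape for name, arr in self.channels().items()}
        if len({s for s in shapes.values()}) != 1:
            raise ValueError(f"channel shape mismatch in {self.fov_id}: {shapes}")
        for name, arr in self.channels().items():
            if arr.ndim != 2:
                raise ValueError(f"channel {name} of {self.fov_id} is not 2-D")
            if np.issubdtype(arr.dtype, np.floating) and not np.isfinite(arr).all():
                raise ValueError(f"non-finite intensities in channel {name} of {self.fov_id}")
            if arr.size and arr.min() < 0:
                raise ValueError(f"negative intensities in channel {name} of {self.fov_id}")
        if self.tile_row < 0 or self.tile_col < 0:
            raise ValueError(f"negative tile position for {self.fov_id}")
        return self


@dataclass
class SampleRecord:
    """One tissue sample: a labelled grid of FoVs from one patient.

    ``tissue_label`` is sample-level ground truth inherited by every FoV.
    Grid convention: row-major, (row, col), 0-based, top-left origin.
    """

    patient_id: str
    sample_id: str
    tissue_label: str
    fovs: list[FovImage] = field(default_factory=list)
    grid_shape: tuple[int, int] = (0, 0)

    def __iter__(self) -> Iterator[FovImage]:
        return iter(self.fovs)

    def __len__(self) -> int:
        return len(self.fovs)

    def validate(self) -> "SampleRecord":
        if self.tissue_label not in TISSUE_LABELS:
            raise ValueError(f"unknown tissue label {self.tissue_label!r}")
        rows, cols = self.grid_shape
        seen: dict[tuple[int, int], str] = {}
        for fov in self.fovs:
            fov.validate()
            pos = (fov.tile_row, fov.tile_col)
            if not (0 <= pos[0] < rows and 0 <= pos[1] < cols):
                raise ValueError(
                    f"FoV {fov.fov_id} at {pos} outside grid {self.grid_shape}"
                )
            if pos in seen:
                raise ValueError(
                    f"duplicate grid position {pos}: {seen[pos]} and {fov.fov_id}"
                )
            seen[pos] = fov.fov_id
        return self
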