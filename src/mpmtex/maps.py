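"""Tiled posterior-probability maps.

Each classified tile is colored by its tumor posterior on a two-segment
linear scale — light blue (p = 0) through mid gray (p = 0.5) to orange
(p = 1) — discarded tiles are dark gray, and grid slots never acquired
stay black.  Rendering is a pure function of (results, discards,
grid shape, palette), so endpoint colors are bit-exact and testable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .discriminant import ClassificationResult, results_frame

ORANGE = (230, 120, 20)        # 100% tumor posterior
MID_GRAY = (128, 128, 128)     # 50%
LIGHT_BLUE = (120, 180, 230)   # 0%
DARK_GRAY = (60, 60, 60)       # discarded before classification
BACKGROUND = (0, 0, 0)         # grid slot never acquired

STATE_ABSENT, STATE_DISCARDED, STATE_CLASSIFIED = 0, 1, 2
_STATE_NAMES = {STATE_ABSENT: "absent", STATE_DISCARDED: "discarded", STATE_CLASSIFIED: "classified"}


def posterior_color(p: float) -> tuple[int, int, int]:
    """Piecewise-linear color for a tumor posterior in [0, 1]."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"posterior {p} outside [0, 1]")
    if p <= 0.5:
        lo, hi, t = LIGHT_BLUE, MID_GRAY, p / 0.5
    else:
        lo, hi, t = MID_GRAY, ORANGE, (p - 0.5) / 0.5
    return tuple(int(np.rint((1 - t) * a + t * b)) for a, b in zip(lo, hi))


@dataclass
class ProbabilityMap:
    """Grid of tile states with posterior values for classified cells."""

    state: np.ndarray      # (rows, cols) int8, STATE_* codes
    posterior: np.ndarray  # (rows, cols) float, NaN unless classified

    @property
    def grid_shape(self) -> tuple[int, int]:
        return tuple(self.state.shape)

    def render(self, cell_px: int = 12) -> np.ndarray:
        """RGB raster with one ``cell_px`` x ``cell_px`` block per tile."""
        rows, cols = self.state.shape
        rgb = np.zeros((rows, cols, 3), dtype=np.uint8)
        rgb[:] = BACKGROUND
        rgb[self.state == STATE_DISCARDED] = DARK_GRAY
        for r, c in zip(*np.nonzero(self.state == STATE_CLASSIFIED)):
            rgb[r, c] = posterior_color(float(self.posterior[r, c]))
        return np.kron(rgb, np.ones((cell_px, cell_px, 1), dtype=np.uint8))

    def to_frame(self) -> pd.DataFrame:
        """CSV twin: tile_row, tile_col, state, posterior_tumor."""
        rows = []
        R, C = self.state.shape
        for r in range(R):
            for c in range(C):
                rows.append(
                    {
                        "tile_row": r,
                        "tile_col": c,
                        "state": _STATE_NAMES[int(self.state[r, c])],
                        "posterior_tumor": (
                            float(self.posterior[r, c])
                            if self.state[r, c] == STATE_CLASSIFIED
                            else np.nan
                        ),
                    }
                )
        return pd.DataFrame(rows)


def assemble_map(
    results: Sequence[ClassificationResult] | pd.DataFrame,
    discards: pd.DataFrame | None,
    grid_shape: tuple[int, int],
) -> ProbabilityMap:
    """Place classified and discarded tiles onto the sample grid.

    A grid position appearing both in ``results`` and in ``discards`` is a
    pipeline inconsistency and raises.
    """
    frame = results if isinstance(results, pd.DataFrame) else results_frame(results)
    rows, cols = grid_shape
    state = np.full((rows, cols), STATE_ABSENT, dtype=np.int8)
    post = np.full((rows, cols), np.nan)

    if discards is not None:
        for _, row in discards.iterrows():
            r, c = int(row["tile_row"]), int(row["tile_col"])
            if not (0 <= r < rows and 0 <= c < cols):
                raise ValueError(f"discard position ({r}, {c}) outside grid {grid_shape}")
            state[r, c] = STATE_DISCARDED

    for _, row in frame.iterrows():
        r, c = int(row["tile_row"]), int(row["tile_col"])
        if not (0 <= r < rows and 0 <= c < cols):
            raise ValueError(f"result position ({r}, {c}) outside grid {grid_shape}")
        if state[r, c] == STATE_DISCARDED:
            raise ValueError(f"position ({r}, {c}) is both classified and discarded")
        if state[r, c] == STATE_CLASSIFIED:
            raise ValueError(f"duplicate classification result at ({r}, {c})")
        p = float(row["posterior_tumor"])
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"posterior {p} at ({r}, {c}) outside [0, 1]")
        state[r, c] = STATE_CLASSIFIED
        post[r, c] = p
    return ProbabilityMap(state=state, posterior=post)


def write_map(pmap: ProbabilityMap, png_path, csv_path=None, cell_px: int = 12) -> None:
    """Write the rendered PNG and (optionally) its CSV twin."""
    iio.imwrite(Path(png_path), pmap.render(cell_px))
    if csv_path is not None:
        pmap.to_frame().to_csv(csv_path, index=False)
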