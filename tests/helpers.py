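"""Independent oracles and small builders shared by the test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd

from mpmtex.features import ORIENTATION_OFFSETS
from mpmtex.types import FovImage


def brute_force_glcm(
    raster: np.ndarray,
    distance: int,
    orientation: int,
    levels: int,
    symmetric: bool,
) -> np.ndarray:
    """Pair-by-pair GLCM enumeration, independent of the vectorized path."""
    x = np.asarray(raster, dtype=float)
    q = np.minimum((x * levels).astype(int), levels - 1)
    dr, dc = ORIENTATION_OFFSETS[orientation]
    dr, dc = dr * distance, dc * distance
    R, C = q.shape
    counts = np.zeros((levels, levels))
    for r in range(R):
        for c in range(C):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < R and 0 <= c2 < C:
                counts[q[r, c], q[r2, c2]] += 1
                if symmetric:
                    counts[q[r2, c2], q[r, c]] += 1
    return counts / counts.sum()


def uniform_fov(shape=(32, 48), value=30000, fov_id="fov", row=0, col=0) -> FovImage:
    """Constant 16-bit tile (passes QC: fully foreground, no saturation)."""
    mk = lambda: np.full(shape, value, dtype=np.uint16)
    return FovImage(cars=mk(), tpef=mk(), shg=mk(), tile_row=row, tile_col=col, fov_id=fov_id)


def gaussian_feature_table(
    rng, mu_normal, mu_tumor, cov, n_samples_per_class=4, images_per_sample=10
) -> pd.DataFrame:
    """Feature table from two known Gaussians; matched patients, one sample
    of each tissue per patient."""
    mu = {"normal": np.asarray(mu_normal, float), "tumor": np.asarray(mu_tumor, float)}
    d = len(mu["normal"])
    cols = [f"f{i}" for i in range(d)]
    rows = []
    for label in ("normal", "tumor"):
        for s in range(n_samples_per_class):
            pid = f"P{s}"
            sid = f"{pid}-{label[0].upper()}"
            X = rng.multivariate_normal(mu[label], cov, size=images_per_sample)
            for i, x in enumerate(X):
                row = {
                    "patient_id": pid,
                    "sample_id": sid,
                    "fov_id": f"{sid}-{i}",
                    "tile_row": 0,
                    "tile_col": i,
                    "tissue_label": label,
                }
                row.update(zip(cols, x))
                rows.append(row)
    return pd.DataFrame(rows)
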