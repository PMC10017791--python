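"""On-disk formats: FoV stacks, sidecar grid metadata, tables, models.

A sample is stored in a directory in one of two dialects:

* ``tiff`` — one multi-page TIFF (``stack.tif``) with three consecutive
  pages per FoV, plus a CSV sidecar (``tiles.csv``) mapping each FoV to
  its grid position and the page index of each channel, plus
  ``sample.json`` with sample metadata;
* ``png`` — one 16-bit grayscale PNG per channel per FoV
  (``<fov_id>_<channel>.png``) with the same two sidecar files.

Channel assignment is always explicit through the sidecar, never guessed
from pixel statistics.  Integer rasters are written as 16-bit and
round-trip losslessly.  Grid convention everywhere: row-major, (row, col),
0-based, top-left origin.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .discriminant import DiscriminantModel
from .features import FeatureSpec
from .types import CHANNELS, FovImage, SampleRecord

LAYOUTS = ("tiff", "png")

_TILES_COLUMNS = ["fov_id", "tile_row", "tile_col"]


def _check_layout(layout: str) -> None:
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; supported: {LAYOUTS}")


def write_fov_stack(sample: SampleRecord, path, layout: str = "tiff") -> None:
    """Write a sample to ``path`` (a directory) in the given dialect."""
    _check_layout(layout)
    sample.validate()
    if not sample.fovs:
        raise ValueError("no FoVs to write")
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)

    meta = {
        "patient_id": sample.patient_id,
        "sample_id": sample.sample_id,
        "tissue_label": sample.tissue_label,
        "grid_shape": list(sample.grid_shape),
        "layout": layout,
        "channel_order": list(CHANNELS),
    }
    (root / "sample.json").write_text(json.dumps(meta, indent=2))

    rows = []
    if layout == "tiff":
        pages = []
        for i, fov in enumerate(sample):
            row = {
                "fov_id": fov.fov_id,
                "tile_row": fov.tile_row,
                "tile_col": fov.tile_col,
            }
            for j, ch in enumerate(CHANNELS):
                row[f"page_{ch}"] = 3 * i + j
                pages.append(np.asarray(fov.channels()[ch]))
            rows.append(row)
        tifffile.imwrite(root / "stack.tif", np.stack(pages))
    else:
        for fov in sample:
            row = {
                "fov_id": fov.fov_id,
                "tile_row": fov.tile_row,
                "tile_col": fov.tile_col,
            }
            for ch in CHANNELS:
                fname = f"{fov.fov_id}_{ch}.png"
                iio.imwrite(root / fname, np.asarray(fov.channels()[ch]))
                row[f"file_{ch}"] = fname
            rows.append(row)
    pd.DataFrame(rows).to_csv(root / "tiles.csv", index=False)


def read_fov_stack(path, layout: str = "tiff") -> SampleRecord:
    """Read a sample written by :func:`write_fov_stack`.

    Errors name the missing channel, a shape mismatch between channels, or
    a duplicate grid position explicitly.
    """
    _check_layout(layout)
    root = Path(path)
    if not root.exists():
        raise FileNotFoundError(f"no such sample directory: {root}")
    meta = json.loads((root / "sample.json").read_text())
    tiles = pd.read_csv(root / "tiles.csv")

    stack = tifffile.imread(root / "stack.tif") if layout == "tiff" else None
    if stack is not None and stack.ndim == 2:
        stack = stack[None]

    fovs = []
    for _, row in tiles.iterrows():
        chans = {}
        for ch in CHANNELS:
            if layout == "tiff":
                key = f"page_{ch}"
                if key not in tiles.columns or pd.isna(row[key]):
                    raise ValueError(f"missing channel {ch.upper()} for FoV {row['fov_id']}")
                page = int(row[key])
                if page >= len(stack):
                    raise ValueError(f"missing channel {ch.upper()}: page {page} absent")
                chans[ch] = np.asarray(stack[page])
            else:
                key = f"file_{ch}"
                if key not in tiles.columns or pd.isna(row[key]):
                    raise ValueError(f"missing channel {ch.upper()} for FoV {row['fov_id']}")
                fpath = root / str(row[key])
                if not fpath.exists():
                    raise ValueError(f"missing channel {ch.upper()}: {fpath.name} absent")
                chans[ch] = np.asarray(iio.imread(fpath))
        shapes = {ch: a.shape for ch, a in chans.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shape mismatch for FoV {row['fov_id']}: {shapes}")
        fovs.append(
            FovImage(
                cars=chans["cars"],
                tpef=chans["tpef"],
                shg=chans["shg"],
                tile_row=int(row["tile_row"]),
                tile_col=int(row["tile_col"]),
                fov_id=str(row["fov_id"]),
            )
        )
    return SampleRecord(
        patient_id=meta["patient_id"],
        sample_id=meta["sample_id"],
        tissue_label=meta["tissue_label"],
        fovs=fovs,
        grid_shape=tuple(meta["grid_shape"]),
    ).validate()


def write_composite(fov: FovImage, per_channel_scale, path) -> None:
    """Write an 8-bit RGB composite: R=CARS, G=TPEF, B=SHG.

    Each channel is min-max normalized to [0, 1], then gain * x + offset is
    clipped to [0, 1] and mapped to 0..255.  ``per_channel_scale`` is three
    (gain, offset) pairs in channel order.
    """
    from .features import normalize_channel

    rgb = np.zeros((*fov.shape, 3), dtype=np.uint8)
    for i, (ch, (gain, offset)) in enumerate(zip(CHANNELS, per_channel_scale)):
        if gain <= 0:
            raise ValueError(f"gain for channel {ch.upper()} must be > 0")
        x = normalize_channel(fov.channels()[ch])
        scaled = np.clip(gain * x + offset, 0.0, 1.0)
        rgb[:, :, i] = np.rint(scaled * 255).astype(np.uint8)
    iio.imwrite(Path(path), rgb)


# ---------------------------------------------------------------------------
# tables and models


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_model(model: DiscriminantModel, path) -> None:
    """Serialize a fitted discriminant model to JSON at full precision."""
    doc = {
        "model_type": model.model_type,
        "classes": list(model.classes),
        "means": model.means.tolist(),
        "covariances": model.covariances.tolist(),
        "priors": model.priors.tolist(),
        "feature_names": list(model.feature_names),
        "ridge": model.ridge,
        "n_per_class": list(model.n_per_class),
        "feature_spec": model.feature_spec.to_dict() if model.feature_spec else None,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_model(path) -> DiscriminantModel:
    doc = json.loads(Path(path).read_text())
    spec = doc.get("feature_spec")
    return DiscriminantModel(
        model_type=doc["model_type"],
        classes=tuple(doc["classes"]),
        means=np.asarray(doc["means"], dtype=np.float64),
        covariances=np.asarray(doc["covariances"], dtype=np.float64),
        priors=np.asarray(doc["priors"], dtype=np.float64),
        feature_names=tuple(doc["feature_names"]),
        ridge=float(doc["ridge"]),
        n_per_class=tuple(doc["n_per_class"]),
        feature_spec=FeatureSpec.from_dict(spec) if spec else None,
    ).validate()
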