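"""Configuration-driven end-to-end runs.

``run_pipeline`` executes simulate/ingest -> QC -> features ->
(crossval | train/test) -> evaluate -> maps from one JSON config and
writes every artifact plus a manifest (config actually used, including
defaults, its hash, the seed and the package version) so a run can be
reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import (
    leave_one_sample_out_cv,
    select_model,
    split_by_patient,
    train_test_evaluate,
)
from .features import STANDARD_SPECS, FeatureSpec, features_table
from .io_formats import read_fov_stack, save_model, write_feature_table, write_fov_stack
from .maps import assemble_map, write_map
from .qc import QcThresholds, filter_sample
from .synthetic import SyntheticConfig, generate_cohort
from .types import SampleRecord

log = logging.getLogger(__name__)

DEFAULTS = {
    "mode": "crossval",            # "crossval" | "train_test" | "select"
    "spec": "reduced_shg",         # name in STANDARD_SPECS or inline dict
    "model_type": "linear",
    "priors_mode": "empirical",
    "distances": [1, 12, 30],
    "glcm_levels": 8,
    "glcm_symmetric": False,
    "qc": {},                      # QcThresholds overrides
    "n_test_matched": 4,           # train_test mode
    "write_images": False,
    "seed": 0,
    "synthetic": {},               # SyntheticConfig overrides; or "input_dir"
}


def _resolve_spec(cfg: dict) -> FeatureSpec:
    spec = cfg["spec"]
    kw = {
        "distances": tuple(cfg["distances"]),
        "glcm_levels": int(cfg["glcm_levels"]),
        "glcm_symmetric": bool(cfg["glcm_symmetric"]),
    }
    if isinstance(spec, str):
        if spec not in STANDARD_SPECS:
            raise ValueError(f"unknown spec {spec!r}; known: {sorted(STANDARD_SPECS)}")
        return STANDARD_SPECS[spec](**kw)
    return FeatureSpec.from_dict({**spec, **{k: v for k, v in kw.items()}})


def load_config(config) -> dict:
    """Merge a config dict or JSON file over the documented defaults."""
    if isinstance(config, (str, Path)):
        user = json.loads(Path(config).read_text())
    else:
        user = dict(config or {})
    unknown = set(user) - set(DEFAULTS) - {"input_dir", "input_layout"}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = {**DEFAULTS, **user}
    if cfg["mode"] not in ("crossval", "train_test", "select"):
        raise ValueError(f"unknown mode {cfg['mode']!r}")
    _resolve_spec(cfg)  # validate early, before any computation
    QcThresholds(**cfg["qc"])
    return cfg


@dataclass
class PipelineResult:
    """Artifacts of one pipeline run (also all written to disk)."""

    outdir: Path
    manifest: dict
    features: pd.DataFrame
    discards: pd.DataFrame
    report: object = None
    selection: pd.DataFrame | None = None


def _load_cohort(cfg: dict) -> list[SampleRecord]:
    if "input_dir" in cfg:
        root = Path(cfg["input_dir"])
        layout = cfg.get("input_layout", "tiff")
        return [read_fov_stack(p, layout) for p in sorted(root.iterdir()) if p.is_dir()]
    syn = dict(cfg["synthetic"])
    syn.setdefault("seed", cfg["seed"])
    return generate_cohort(SyntheticConfig.from_dict(syn))


def run_pipeline(config, outdir) -> PipelineResult:
    """Execute the configured pipeline and write artifacts under outdir."""
    cfg = load_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    cfg_json = json.dumps(cfg, sort_keys=True)
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": cfg["seed"],
        "package_version": __version__,
        "stages": [],
    }

    log.info("stage: cohort")
    cohort = _load_cohort(cfg)
    manifest["stages"].append({"stage": "cohort", "n_samples": len(cohort)})
    if cfg["write_images"]:
        for sample in cohort:
            write_fov_stack(sample, out / "cohort" / sample.sample_id, "tiff")

    log.info("stage: qc")
    thresholds = QcThresholds(**cfg["qc"])
    kept, discard_frames = [], []
    for sample in cohort:
        ks, table = filter_sample(sample, thresholds)
        kept.append(ks)
        if len(table):
            table.insert(0, "sample_id", sample.sample_id)
            discard_frames.append(table)
    discards = (
        pd.concat(discard_frames, ignore_index=True)
        if discard_frames
        else pd.DataFrame(columns=["sample_id", "fov_id", "tile_row", "tile_col", "reason"])
    )
    discards.to_csv(out / "discards.csv", index=False)
    manifest["stages"].append({"stage": "qc", "n_discarded": len(discards)})

    log.info("stage: features")
    spec = _resolve_spec(cfg)
    table = features_table([s for s in kept if len(s)], spec)
    write_feature_table(table, out / "features.csv")
    manifest["stages"].append({"stage": "features", "n_rows": len(table), "n_features": spec.n_features()})

    selection = None
    log.info("stage: %s", cfg["mode"])
    if cfg["mode"] == "select":
        kw = {
            "distances": tuple(cfg["distances"]),
            "glcm_levels": int(cfg["glcm_levels"]),
            "glcm_symmetric": bool(cfg["glcm_symmetric"]),
        }
        full_table = features_table([s for s in kept if len(s)], FeatureSpec.full(**kw))
        candidates = {name: make(**kw) for name, make in STANDARD_SPECS.items()}
        best_spec, best_type, selection = select_model(full_table, candidates)
        selection.to_csv(out / "selection.csv", index=False)
        report, predictions = leave_one_sample_out_cv(
            full_table, candidates[best_spec], best_type, cfg["priors_mode"]
        )
        manifest["stages"].append(
            {"stage": "select", "best_spec": best_spec, "best_model_type": best_type}
        )
    elif cfg["mode"] == "crossval":
        report, predictions = leave_one_sample_out_cv(
            table, spec, cfg["model_type"], cfg["priors_mode"]
        )
    else:  # train_test
        rng = np.random.default_rng(cfg["seed"])
        plan = split_by_patient(table, int(cfg["n_test_matched"]), rng)
        model, report, predictions = train_test_evaluate(
            table, plan, spec, cfg["model_type"], cfg["priors_mode"]
        )
        save_model(model, out / "model.json")
        manifest["stages"].append(
            {"stage": "split", "test_patients": list(plan.test_patients)}
        )

    predictions.to_csv(out / "predictions.csv", index=False)
    (out / "report.json").write_text(report.to_json())
    (out / "report.txt").write_text(report.to_text() + "\n")
    report.per_sample.to_csv(out / "per_sample.csv", index=False)

    log.info("stage: maps")
    maps_dir = out / "maps"
    maps_dir.mkdir(exist_ok=True)
    grid_by_sample = {s.sample_id: s.grid_shape for s in cohort}
    for sid, sub in predictions.groupby("sample_id"):
        disc = discards[discards["sample_id"] == sid] if len(discards) else None
        pmap = assemble_map(sub, disc, grid_by_sample[sid])
        write_map(pmap, maps_dir / f"{sid}.png", maps_dir / f"{sid}.csv")
    manifest["stages"].append({"stage": "maps", "n_maps": predictions["sample_id"].nunique()})

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return PipelineResult(
        outdir=out,
        manifest=manifest,
        features=table,
        discards=discards,
        report=report,
        selection=selection,
    )
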