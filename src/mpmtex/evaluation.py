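"""Cross-validation, patient-level splitting, model selection and metrics.

Two granularities of hold-out mirror the study design exactly:

* *leave-one-sample-out cross-validation* (LOSO-CV): all images of one
  tissue sample are classified by a model trained on the images of every
  other sample — the benchmark used to select the classifier variant and
  the per-channel feature subsets;
* *patient-level train/test split*: every image of a patient lands on one
  side only, and the test set contains only patients with matched tumor
  and normal samples.

Metrics use tumor as the positive class.  Pooled (image-level)
sensitivity/specificity coincide with the per-class correct rates; macro
averages over samples are reported alongside because the two aggregation
conventions genuinely differ on unbalanced cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .discriminant import (
    ClassificationResult,
    DiscriminantModel,
    classify_images,
    fit_discriminant,
    results_frame,
)
from .features import FeatureSpec

PROVENANCE = ("patient_id", "sample_id", "fov_id", "tile_row", "tile_col", "tissue_label")


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint patient-level train/test assignment."""

    test_patients: tuple[str, ...]
    train_patients: tuple[str, ...]

    def __post_init__(self):
        if set(self.test_patients) & set(self.train_patients):
            raise ValueError("train and test patients overlap")


@dataclass
class EvaluationReport:
    """Confusion counts and derived rates, pooled and per-sample."""

    tp: int
    tn: int
    fp: int
    fn: int
    per_sample: pd.DataFrame = field(repr=False)  # sample_id, patient_id, tissue_label, n_images, fraction_correct
    frac_true_posterior_ge_95: float = 0.0
    frac_true_posterior_ge_99: float = 0.0

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def correct_rate(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        """Pooled tumor recall (= correct rate for tumor images)."""
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        """Pooled normal recall (= correct rate for normal images)."""
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def tumor_correct_rate(self) -> float:
        return self.sensitivity

    @property
    def normal_correct_rate(self) -> float:
        return self.specificity

    def _macro(self, label: str) -> float:
        sub = self.per_sample[self.per_sample["tissue_label"] == label]
        return float(sub["fraction_correct"].mean()) if len(sub) else float("nan")

    @property
    def macro_sensitivity(self) -> float:
        """Unweighted mean per-sample correct fraction over tumor samples."""
        return self._macro("tumor")

    @property
    def macro_specificity(self) -> float:
        return self._macro("normal")

    def to_dict(self) -> dict:
        return {
            "n_images": self.n,
            "confusion": {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn},
            "correct_rate": self.correct_rate,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "tumor_correct_rate": self.tumor_correct_rate,
            "normal_correct_rate": self.normal_correct_rate,
            "macro_sensitivity": self.macro_sensitivity,
            "macro_specificity": self.macro_specificity,
            "frac_true_posterior_ge_95": self.frac_true_posterior_ge_95,
            "frac_true_posterior_ge_99": self.frac_true_posterior_ge_99,
            "per_sample": self.per_sample.to_dict(orient="records"),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def to_text(self) -> str:
        lines = [
            f"images: {self.n}  correct rate: {self.correct_rate:.3f}",
            f"sensitivity (tumor recall): {self.sensitivity:.3f}"
            f"  specificity (normal recall): {self.specificity:.3f}",
            f"macro per-sample: tumor {self.macro_sensitivity:.3f}"
            f"  normal {self.macro_specificity:.3f}",
            f"true-class posterior >= 0.95: {self.frac_true_posterior_ge_95:.3f}"
            f"  >= 0.99: {self.frac_true_posterior_ge_99:.3f}",
        ]
        return "\n".join(lines)


def evaluate(results: Sequence[ClassificationResult] | pd.DataFrame) -> EvaluationReport:
    """Build an evaluation report from classified images with known truth."""
    frame = results if isinstance(results, pd.DataFrame) else results_frame(results)
    if len(frame) == 0:
        raise ValueError("no classification results to evaluate")
    if frame["truth"].isna().any():
        raise ValueError("every result needs a truth label")
    truth = frame["truth"].to_numpy()
    pred = frame["predicted"].to_numpy()
    post = frame["posterior_tumor"].to_numpy(dtype=float)

    tp = int(np.sum((truth == "tumor") & (pred == "tumor")))
    fn = int(np.sum((truth == "tumor") & (pred == "normal")))
    tn = int(np.sum((truth == "normal") & (pred == "normal")))
    fp = int(np.sum((truth == "normal") & (pred == "tumor")))

    p_true = np.where(truth == "tumor", post, 1.0 - post)
    correct = truth == pred
    per_sample = (
        frame.assign(correct=correct)
        .groupby(["sample_id", "patient_id", "truth"], as_index=False)
        .agg(n_images=("correct", "size"), fraction_correct=("correct", "mean"))
        .rename(columns={"truth": "tissue_label"})
    )
    return EvaluationReport(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        per_sample=per_sample,
        frac_true_posterior_ge_95=float(np.mean(p_true >= 0.95)),
        frac_true_posterior_ge_99=float(np.mean(p_true >= 0.99)),
    )


def _patient_labels(table: pd.DataFrame) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for pid, lab in zip(table["patient_id"], table["tissue_label"]):
        out.setdefault(pid, set()).add(lab)
    return out


def split_by_patient(
    table: pd.DataFrame, n_test_matched: int, rng: np.random.Generator
) -> SplitPlan:
    """Randomly assign matched patients to the test set.

    Only patients with both tissue types are eligible for testing; every
    other patient trains.  Deterministic under a seeded generator.
    """
    labels = _patient_labels(table)
    matched = sorted(p for p, labs in labels.items() if labs == {"normal", "tumor"})
    if len(matched) < n_test_matched:
        raise ValueError(
            f"insufficient matched patients: need {n_test_matched}, have {len(matched)}"
        )
    test = tuple(sorted(rng.choice(matched, size=n_test_matched, replace=False)))
    train = tuple(sorted(set(labels) - set(test)))
    if not train:
        raise ValueError("no patients left for training")
    return SplitPlan(test_patients=test, train_patients=train)


def _feature_columns(table: pd.DataFrame, spec: FeatureSpec | None) -> list[str]:
    if spec is not None:
        cols = list(spec.feature_names())
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise ValueError(f"feature table lacks columns {missing[:5]}")
        return cols
    return [c for c in table.columns if c not in PROVENANCE]


def leave_one_sample_out_cv(
    table: pd.DataFrame,
    spec: FeatureSpec | None = None,
    model_type: str = "linear",
    priors_mode: str = "empirical",
) -> tuple[EvaluationReport, pd.DataFrame]:
    """LOSO-CV over a cohort feature table.

    One fold per sample: fit on all images of every other sample, classify
    the held-out sample's images.  Returns the pooled report plus the
    per-image out-of-fold predictions.
    """
    cols = _feature_columns(table, spec)
    sample_ids = table["sample_id"].unique()
    if len(sample_ids) < 2:
        raise ValueError("LOSO-CV needs at least 2 samples")
    all_results: list[pd.DataFrame] = []
    for sid in sample_ids:
        held = table["sample_id"] == sid
        train = table[~held]
        if train["tissue_label"].nunique() < 2:
            raise ValueError(f"training set for fold {sid!r} lacks a class")
        model = fit_discriminant(
            train[list(PROVENANCE) + cols],
            model_type=model_type,
            priors_mode=priors_mode,
            feature_names=cols,
        )
        res = classify_images(model, table[held])
        all_results.append(results_frame(res))
    predictions = pd.concat(all_results, ignore_index=True)
    return evaluate(predictions), predictions


def train_test_evaluate(
    table: pd.DataFrame,
    plan: SplitPlan,
    spec: FeatureSpec | None = None,
    model_type: str = "linear",
    priors_mode: str = "empirical",
) -> tuple[DiscriminantModel, EvaluationReport, pd.DataFrame]:
    """Fit on training patients, evaluate on held-out test patients."""
    cols = _feature_columns(table, spec)
    is_test = table["patient_id"].isin(plan.test_patients)
    train, test = table[~is_test], table[is_test]
    if len(test) == 0:
        raise ValueError("empty test set")
    model = fit_discriminant(
        train[list(PROVENANCE) + cols],
        model_type=model_type,
        priors_mode=priors_mode,
        feature_names=cols,
    )
    predictions = results_frame(classify_images(model, test))
    return model, evaluate(predictions), predictions


def select_model(
    table: pd.DataFrame,
    candidate_specs: dict[str, FeatureSpec],
    model_types: Sequence[str] = ("linear", "quadratic"),
    priors_mode: str = "empirical",
) -> tuple[str, str, pd.DataFrame]:
    """Pick (feature spec, model type) by LOSO-CV correct rate.

    Ties break toward fewer features, then linear over quadratic.  Returns
    the winning spec name, model type and the full selection table.
    """
    if not candidate_specs:
        raise ValueError("no candidate specs")
    rows = []
    for name, spec in candidate_specs.items():
        for mt in model_types:
            report, _ = leave_one_sample_out_cv(table, spec, mt, priors_mode)
            rows.append(
                {
                    "spec": name,
                    "model_type": mt,
                    "n_features": spec.n_features(),
                    "correct_rate": report.correct_rate,
                    "sensitivity": report.sensitivity,
                    "specificity": report.specificity,
                }
            )
    selection = pd.DataFrame(rows)
    order = selection.assign(
        _linear=(selection["model_type"] == "linear").astype(int)
    ).sort_values(
        by=["correct_rate", "n_features", "_linear"],
        ascending=[False, True, False],
        kind="mergesort",
    )
    best = order.iloc[0]
    return str(best["spec"]), str(best["model_type"]), selection
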