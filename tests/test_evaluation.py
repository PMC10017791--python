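"""Metrics, splits, cross-validation and model selection."""

import numpy as np
import pandas as pd
import pytest

from helpers import gaussian_feature_table
from mpmtex.evaluation import (
    evaluate,
    leave_one_sample_out_cv,
    select_model,
    split_by_patient,
    train_test_evaluate,
    SplitPlan,
)
from mpmtex.features import FeatureSpec


def _results(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "fov_id", "patient_id", "sample_id", "tile_row", "tile_col",
            "posterior_tumor", "predicted", "truth",
        ],
    )


def _make_results(tp, tn, fp, fn):
    rows = []
    i = 0
    for n, pred, truth in [
        (tp, "tumor", "tumor"), (tn, "normal", "normal"),
        (fp, "tumor", "normal"), (fn, "normal", "tumor"),
    ]:
        for _ in range(n):
            post = 0.9 if pred == "tumor" else 0.1
            rows.append([f"f{i}", "P", f"S-{truth}", 0, i, post, pred, truth])
            i += 1
    return _results(rows)


class TestEvaluate:
    def test_hand_arithmetic(self):
        rep = evaluate(_make_results(tp=9, tn=8, fp=2, fn=1))
        assert rep.correct_rate == pytest.approx(0.85)
        assert rep.sensitivity == pytest.approx(0.9)
        assert rep.specificity == pytest.approx(0.8)
        assert rep.tumor_correct_rate == rep.sensitivity
        assert rep.normal_correct_rate == rep.specificity

    def test_all_correct(self):
        rep = evaluate(_make_results(tp=5, tn=5, fp=0, fn=0))
        assert rep.correct_rate == 1.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0
        assert rep.frac_true_posterior_ge_95 == 0.0  # posteriors at 0.9/0.1

    def test_single_sample_half_correct(self):
        rows = [
            [f"f{i}", "P", "S", 0, i, 0.9, "tumor" if i < 2 else "normal", "tumor"]
            for i in range(4)
        ]
        rep = evaluate(_results(rows))
        assert len(rep.per_sample) == 1
        assert rep.per_sample.iloc[0]["fraction_correct"] == 0.5

    def test_posterior_confidence_fractions(self):
        rows = [
            ["a", "P", "S", 0, 0, 0.999, "tumor", "tumor"],
            ["b", "P", "S", 0, 1, 0.96, "tumor", "tumor"],
            ["c", "P", "S", 0, 2, 0.02, "normal", "normal"],
            ["d", "P", "S", 0, 3, 0.60, "tumor", "tumor"],
        ]
        rep = evaluate(_results(rows))
        assert rep.frac_true_posterior_ge_95 == 0.75
        assert rep.frac_true_posterior_ge_99 == 0.25

    def test_pooled_rate_is_weighted_mean_of_class_rates(self, rng):
        for _ in range(100):
            tp, tn, fp, fn = rng.integers(1, 60, 4)
            rep = evaluate(_make_results(int(tp), int(tn), int(fp), int(fn)))
            n_tum, n_nor = tp + fn, tn + fp
            weighted = (
                n_tum * rep.tumor_correct_rate + n_nor * rep.normal_correct_rate
            ) / (n_tum + n_nor)
            assert rep.correct_rate == pytest.approx(weighted, abs=1e-12)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="no classification results"):
            evaluate(_results([]))

    def test_missing_truth_errors(self):
        rows = [["a", "P", "S", 0, 0, 0.9, "tumor", None]]
        with pytest.raises(ValueError, match="truth"):
            evaluate(_results(rows))


class TestSplit:
    def _table(self):
        rows = []
        for p in range(6):
            labels = (
                ["normal", "tumor"] if p < 4 else (["tumor"] if p == 4 else ["normal"])
            )
            for lab in labels:
                rows.append({"patient_id": f"P{p}", "tissue_label": lab})
        return pd.DataFrame(rows)

    def test_split_sizes_and_disjointness(self):
        plan = split_by_patient(self._table(), 2, np.random.default_rng(3))
        assert len(plan.test_patients) == 2
        assert not set(plan.test_patients) & set(plan.train_patients)
        assert len(plan.test_patients) + len(plan.train_patients) == 6

    def test_unmatched_patient_never_in_test(self):
        for seed in range(10):
            plan = split_by_patient(self._table(), 3, np.random.default_rng(seed))
            assert "P4" not in plan.test_patients
            assert "P5" not in plan.test_patients

    def test_deterministic_under_seed(self):
        a = split_by_patient(self._table(), 2, np.random.default_rng(7))
        b = split_by_patient(self._table(), 2, np.random.default_rng(7))
        assert a == b

    def test_insufficient_matched_errors(self):
        with pytest.raises(ValueError, match="insufficient matched"):
            split_by_patient(self._table(), 5, np.random.default_rng(0))

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SplitPlan(test_patients=("P1",), train_patients=("P1", "P2"))


class TestLoso:
    def test_fold_count_equals_sample_count(self, rng):
        table = gaussian_feature_table(
            rng, [0, 0], [2, 2], np.eye(2), n_samples_per_class=3, images_per_sample=5
        )
        report, preds = leave_one_sample_out_cv(table)
        assert preds["sample_id"].nunique() == 6
        assert len(preds) == len(table)
        assert len(report.per_sample) == 6

    def test_perfectly_separable_cohort(self, rng):
        table = gaussian_feature_table(
            rng, [0, 0, 0], [50, 50, 50], np.eye(3), 4, 8
        )
        report, _ = leave_one_sample_out_cv(table)
        assert report.correct_rate == 1.0

    def test_prior_only_classifier_majority_rate(self):
        # constant features carry no information, so every fold predicts the
        # training majority class; with 4 tumor vs 2 normal samples the
        # pooled correct rate is exactly the majority-class rate 2/3
        rows = []
        for label, count in (("tumor", 4), ("normal", 2)):
            for s in range(count):
                sid = f"{label}{s}"
                for i in range(10):
                    rows.append(
                        {
                            "patient_id": sid, "sample_id": sid,
                            "fov_id": f"{sid}-{i}", "tile_row": 0, "tile_col": i,
                            "tissue_label": label, "f0": 1.0, "f1": 2.0,
                        }
                    )
        report, _ = leave_one_sample_out_cv(pd.DataFrame(rows))
        assert report.correct_rate == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_fold_missing_class_errors(self, rng):
        table = gaussian_feature_table(rng, [0], [1], np.eye(1), 1, 5)
        with pytest.raises(ValueError, match="lacks a class"):
            leave_one_sample_out_cv(table)


class TestTrainTest:
    def test_patient_holdout_end_to_end(self, rng):
        table = gaussian_feature_table(rng, [0, 0], [30, 30], np.eye(2), 5, 6)
        plan = split_by_patient(table, 2, np.random.default_rng(0))
        model, report, preds = train_test_evaluate(table, plan)
        assert set(preds["patient_id"]) == set(plan.test_patients)
        assert report.correct_rate == 1.0
        assert model.n_per_class == (18, 18)


class TestSelectModel:
    def test_selection_table_bookkeeping(self, small_cohort):
        from mpmtex.features import features_table

        kw = dict(distances=(1, 2))
        candidates = {
            "full": FeatureSpec.full(**kw),
            "reduced_shg": FeatureSpec.reduced_shg(**kw),
            "cars_only": FeatureSpec.cars_only(**kw),
        }
        table = features_table(small_cohort, FeatureSpec.full(**kw))
        best_spec, best_type, selection = select_model(table, candidates)
        assert len(selection) == 6  # 3 specs x 2 model types
        assert best_spec in candidates
        assert best_type in ("linear", "quadratic")
        assert selection["correct_rate"].max() == pytest.approx(
            selection.set_index(["spec", "model_type"]).loc[
                (best_spec, best_type), "correct_rate"
            ]
        )

    def test_single_candidate_returned(self, rng):
        table = gaussian_feature_table(rng, [0, 0], [9, 9], np.eye(2), 3, 5)
        table = table.rename(columns={"f0": "cars_mean", "f1": "cars_sd"})
        only = FeatureSpec(channels={"cars": ("mean", "sd")}, distances=())
        best_spec, best_type, selection = select_model(
            table, {"only": only}, model_types=("linear",)
        )
        assert best_spec == "only" and best_type == "linear"
        assert len(selection) == 1
        assert selection.iloc[0]["correct_rate"] == 1.0

    def test_no_candidates_errors(self, rng):
        table = gaussian_feature_table(rng, [0], [1], np.eye(1), 2, 4)
        with pytest.raises(ValueError, match="no candidate"):
            select_model(table, {})

    def test_tie_breaks_prefer_fewer_features_then_linear(self, rng):
        # two identical candidates except feature count: on a perfectly
        # separable cohort both reach rate 1.0 and the smaller wins
        table = gaussian_feature_table(rng, [0, 0, 0], [40, 40, 40], np.eye(3), 3, 6)
        table = table.rename(
            columns={"f0": "cars_mean", "f1": "cars_sd", "f2": "cars_kurtosis"}
        )
        big = FeatureSpec(channels={"cars": ("mean", "sd", "kurtosis")}, distances=())
        small = FeatureSpec(channels={"cars": ("mean", "sd")}, distances=())
        best_spec, best_type, sel = select_model(
            table, {"big": big, "small": small}
        )
        assert (sel["correct_rate"] == 1.0).all()
        assert best_spec == "small"
        assert best_type == "linear"
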