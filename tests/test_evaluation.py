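"""Fold construction, aggregation, confusion metrics, CV mechanics, ANOVA."""

import numpy as np
import pandas as pd
import pytest

from trodnet import assembly, evaluation
from trodnet.assembly import DatasetTensor
from trodnet.datasets import load_clinical_cohort, longitudinal_anova_table
from trodnet.evaluation import (
    FoldPlan,
    aggregate_subject,
    audit_no_leakage,
    confusion_metrics,
    make_folds,
    mixed_anova,
    run_cv,
    summarize_subject_predictions,
)


class TestMakeFolds:
    def test_stratified_partition_54_subjects(self):
        """26 concussed + 28 controls into 10 folds: sizes 5-6, classes 2-3
        per fold."""
        sids = np.array([f"s{i:02d}" for i in range(54)])
        labels = np.array([1] * 26 + [0] * 28)
        plan = make_folds(sids, labels, k=10, seed=1)
        assert plan.k == 10
        sizes = [len(f) for f in plan.folds]
        assert set(sizes) <= {5, 6}
        for fold in plan.folds:
            n_conc = sum(labels[sids.tolist().index(s)] for s in fold)
            assert 2 <= n_conc <= 3
            assert 2 <= len(fold) - n_conc <= 3

    def test_partition_property(self):
        sids = np.array([f"s{i}" for i in range(23)])
        labels = np.array([0, 1] * 11 + [0])
        plan = make_folds(sids, labels, k=5, seed=0)
        all_s = [s for f in plan.folds for s in f]
        assert sorted(all_s) == sorted(sids)
        assert len(set(all_s)) == len(all_s)

    def test_deterministic(self):
        sids = [f"s{i}" for i in range(20)]
        labels = [0, 1] * 10
        assert make_folds(sids, labels, seed=3) == make_folds(sids, labels, seed=3)

    def test_k_below_2_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b", "c"], [0, 1, 0], k=1)


class TestAggregation:
    @pytest.mark.parametrize(
        "n_concussed, n_total, expected",
        [(19, 36, 1), (18, 36, 0), (36, 36, 1), (0, 36, 0), (1, 1, 1)],
    )
    def test_majority_rule_with_strict_tie_break(self, n_concussed, n_total, expected):
        labels = [1] * n_concussed + [0] * (n_total - n_concussed)
        assert aggregate_subject(labels) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_subject([])


class TestConfusionMetrics:
    def test_published_counts_reproduce_headline_metrics(self):
        """22/4/24/4 -> sensitivity 84.6%, specificity 85.7%, accuracy 85%."""
        c = confusion_metrics(tp=22, fn=4, tn=24, fp=4)
        assert round(100 * c.sensitivity, 1) == 84.6
        assert round(100 * c.specificity, 1) == 85.7
        assert round(100 * c.accuracy) == 85

    @pytest.mark.parametrize("n", [1, 7])
    def test_perfect_and_inverted(self, n):
        perfect = confusion_metrics(n, 0, n, 0)
        assert (perfect.sensitivity, perfect.specificity, perfect.accuracy) == (1, 1, 1)
        inverted = confusion_metrics(0, n, 0, n)
        assert (inverted.sensitivity, inverted.specificity, inverted.accuracy) == (0, 0, 0)

    def test_empty_class_flagged_as_nan(self):
        c = confusion_metrics(0, 0, 3, 1)
        assert np.isnan(c.sensitivity)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(-1, 0, 0, 0)


@pytest.fixture(scope="module")
def quick_cv(tiny_tensor, small_model_config):
    """One CV run on the tiny cohort with a reduced training schedule."""
    return run_cv(tiny_tensor, config=small_model_config, seed=5, k=4, keep_models=True)


class TestRunCV:
    def test_each_subject_predicted_exactly_once(self, quick_cv, tiny_tensor):
        seen = [p.subject_id for p in quick_cv.predictions]
        assert sorted(seen) == sorted(tiny_tensor.subject_ids)

    def test_confusion_consistent_with_aggregated_labels(self, quick_cv):
        conf = summarize_subject_predictions(quick_cv.predictions)
        assert conf.as_dict() == quick_cv.confusion.as_dict()

    def test_pooled_trial_accuracy_is_weighted_subject_mean(self, quick_cv):
        preds = quick_cv.predictions
        weighted = sum(p.trial_accuracy * p.trial_labels.size for p in preds) / sum(
            p.trial_labels.size for p in preds
        )
        assert quick_cv.trial_accuracy == pytest.approx(weighted)

    def test_corrupted_fold_plan_aborts(self, tiny_tensor, small_model_config):
        sids = list(tiny_tensor.subject_ids)
        bad = FoldPlan(folds=(tuple(sids[:3]), tuple(sids[2:])), seed=0)
        with pytest.raises(RuntimeError, match="leakage"):
            run_cv(tiny_tensor, config=small_model_config, fold_plan=bad)

    def test_leakage_audit_detects_missing_subject(self, tiny_tensor):
        sids = list(tiny_tensor.subject_ids)
        partial = FoldPlan(folds=(tuple(sids[:3]), tuple(sids[3:-1])), seed=0)
        with pytest.raises(RuntimeError, match="without fold"):
            audit_no_leakage(partial, tiny_tensor)


class TestLongitudinal:
    def test_identical_second_tensor_reproduces_first_accuracies(
        self, quick_cv, tiny_tensor
    ):
        """Same inputs through the same fold model give the same results."""
        second = DatasetTensor(
            tiny_tensor.X.copy(),
            tiny_tensor.labels.copy(),
            tiny_tensor.subjects.copy(),
            session="second",
        )
        table = evaluation.evaluate_longitudinal(quick_cv, second)
        first = {p.subject_id: p.trial_accuracy for p in quick_cv.predictions}
        for _, row in table.iterrows():
            assert row["accuracy_t2"] == pytest.approx(first[row["subject_id"]])

    def test_unknown_subject_rejected(self, quick_cv, tiny_tensor):
        ghost = DatasetTensor(
            tiny_tensor.X[:36],
            tiny_tensor.labels[:36],
            np.array(["nobody"] * 36),
            session="second",
        )
        with pytest.raises(KeyError):
            evaluation.evaluate_longitudinal(quick_cv, ghost)


def _projection_anova(table):
    """Independent oracle: explicit design-matrix projections for the
    split-plot model (between factor on subject sums, within factor and
    interaction on date differences)."""
    g = (table["recovery"] == table["recovery"].iloc[0]).to_numpy()
    t1 = table["accuracy_t1"].to_numpy()
    t2 = table["accuracy_t2"].to_numpy()
    n = len(table)

    def ols_ss(y, X_full, X_null):
        def proj(X):
            return X @ np.linalg.pinv(X.T @ X) @ X.T

        r_full = y - proj(X_full) @ y
        r_null = y - proj(X_null) @ y
        return (r_null @ r_null) - (r_full @ r_full), r_full @ r_full

    ones = np.ones((n, 1))
    G = np.column_stack([ones[:, 0], g.astype(float)])
    s = t1 + t2
    ss_rec, sse_s = ols_ss(s, G, ones)
    d = t2 - t1
    ss_int, sse_d = ols_ss(d, G, ones)
    # within main effect: weighted grand mean of differences vs zero
    ss_date = n * d.mean() ** 2
    _, sse_d_full = ols_ss(d, G, ones)
    df2 = n - 2
    return {
        "recovery": ss_rec / (sse_s / df2),
        "date": ss_date / (sse_d / df2),
        "interaction": ss_int / (sse_d / df2),
    }


class TestMixedAnova:
    def test_clinical_longitudinal_table_statistics(self):
        """The bundled 19-subject longitudinal table: Testing-Date main
        effect F(1,17) ~ 9, recovery ~ 4, interaction < 1."""
        table = longitudinal_anova_table()
        res = mixed_anova(table).set_index("effect")
        assert res.loc["date", "df1"] == 1 and res.loc["date", "df2"] == 17
        assert res.loc["date", "F"] == pytest.approx(9.1414, abs=1e-3)
        assert res.loc["recovery", "F"] == pytest.approx(4.0066, abs=1e-3)
        assert res.loc["interaction", "F"] == pytest.approx(0.4885, abs=1e-3)
        assert res.loc["date", "p"] < 0.01

    def test_matches_projection_oracle_on_random_unbalanced_data(self):
        rng = np.random.default_rng(4)
        for trial in range(5):
            n1, n2 = rng.integers(3, 9, size=2)
            table = pd.DataFrame(
                {
                    "subject_id": [f"s{i}" for i in range(n1 + n2)],
                    "recovery": ["SR"] * n1 + ["NSR"] * n2,
                    "accuracy_t1": rng.normal(70, 15, n1 + n2),
                    "accuracy_t2": rng.normal(60, 15, n1 + n2),
                }
            )
            res = mixed_anova(table).set_index("effect")["F"]
            oracle = _projection_anova(table)
            for effect in ("recovery", "date", "interaction"):
                assert res[effect] == pytest.approx(oracle[effect], rel=1e-6)

    def test_equal_group_shifts_give_zero_interaction(self):
        """Both groups' date effects share the same mean, so the
        interaction sum of squares vanishes exactly (the residual stays
        positive via group-mean-centred jitter)."""
        rng = np.random.default_rng(9)
        base = rng.normal(70, 10, 12)
        jitter = rng.normal(0, 3, 12)
        jitter[:5] -= jitter[:5].mean()
        jitter[5:] -= jitter[5:].mean()
        table = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(12)],
                "recovery": ["SR"] * 5 + ["NSR"] * 7,
                "accuracy_t1": base,
                "accuracy_t2": base - 7.5 + jitter,
            }
        )
        res = mixed_anova(table).set_index("effect")
        assert res.loc["interaction", "F"] == pytest.approx(0.0, abs=1e-10)
        assert res.loc["date", "F"] > 10  # the common shift dominates

    def test_type_three_weights_groups_equally(self):
        table = longitudinal_anova_table()
        res3 = mixed_anova(table, ss_type=3).set_index("effect")
        assert res3.loc["date", "F"] == pytest.approx(8.2667, abs=1e-3)
        # between factor and interaction agree across types here
        res2 = mixed_anova(table).set_index("effect")
        assert res3.loc["recovery", "F"] == pytest.approx(res2.loc["recovery", "F"], rel=1e-6)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            mixed_anova(pd.DataFrame({"subject_id": [], "recovery": []}))

    def test_single_group_rejected(self):
        table = pd.DataFrame(
            {
                "subject_id": ["a", "b", "c"],
                "recovery": ["SR"] * 3,
                "accuracy_t1": [1.0, 2.0, 3.0],
                "accuracy_t2": [1.0, 2.0, 3.0],
            }
        )
        with pytest.raises(ValueError, match="two recovery groups"):
            mixed_anova(table)


class TestClinicalCohortTable:
    def test_aggregates_match_published_summary(self):
        """Column means reproduce the published aggregate rows."""
        df = load_clinical_cohort()
        assert len(df) == 26
        assert df["longitudinal"].sum() == 19
        assert round(df["trial_accuracy_t1"].mean(), 1) == 70.6
        assert round(df["days_since_injury_t1"].mean(), 2) == 20.15
        long = df[df["longitudinal"]]
        sr = long[long["symptom_resolution"] == "SR"]
        nsr = long[long["symptom_resolution"] == "NSR"]
        assert (len(sr), len(nsr)) == (8, 11)
        assert round(sr["trial_accuracy_t2"].mean()) == 76
        assert round(nsr["trial_accuracy_t2"].mean(), 1) == 53.8
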