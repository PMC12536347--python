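"""Normalisation, metrics, grids and the two cross-validation regimes."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cogload.classification import (
    CVReport,
    accuracy,
    apply_minmax,
    expand_grid,
    fit_minmax,
    loo_cv,
    make_estimator,
    normalize_features,
    permutation_null,
    personal_cv,
    weighted_f1,
    write_report,
)
from cogload.errors import InvalidArgumentError
from cogload.labels import ClassificationProblem, FeatureSetSpec
from tests.conftest import make_feature_table

PROBLEM2 = ClassificationProblem(2)
LOGISTIC = ("logistic", {"solver": "lbfgs", "penalty": "l2"})


def _spec(table) -> FeatureSetSpec:
    from cogload.labels import feature_columns

    return FeatureSetSpec("test", tuple(feature_columns(table)))


class TestGrids:
    def test_tree_grid_has_61_depths(self):
        grid = expand_grid("tree")
        depths = sorted({g["max_depth"] for g in grid})
        assert depths == list(range(5, 306, 5))
        assert len(depths) == 61
        assert len(grid) == 2 * 2 * 61

    def test_logistic_grid_prunes_invalid_combinations(self):
        grid = expand_grid("logistic")
        assert {"solver": "lbfgs", "penalty": "l1"} not in grid
        assert {"solver": "liblinear", "penalty": "none"} not in grid
        assert {"solver": "saga", "penalty": "l1"} in grid
        assert len(grid) == 9

    def test_mlp_knn_svm_grid_sizes(self):
        assert len(expand_grid("mlp")) == 3 * 4
        assert len(expand_grid("knn")) == 6 * 30 * 2
        assert len(expand_grid("knn", knn_full_leaf=True)) == 50 * 30 * 2
        assert len(expand_grid("linear_svm")) == 2 * 7

    @pytest.mark.parametrize("family", ["tree", "logistic", "mlp", "knn",
                                        "linear_svm"])
    def test_every_grid_point_instantiates_and_fits(self, family, rng):
        X = rng.standard_normal((30, 4))
        y = np.repeat([0, 1], 15)
        params = expand_grid(family)[0]
        est = make_estimator(family, params, seed=0)
        est.fit(X, y)
        assert len(est.predict(X)) == 30


class TestGridYaml:
    def test_yaml_grid_round_trip(self, tmp_path):
        from cogload.classification import grid_from_yaml

        path = tmp_path / "grid.yaml"
        path.write_text(
            "logistic:\n- {solver: lbfgs, penalty: l2}\n"
            "tree:\n- {criterion: gini, splitter: best, max_depth: 5}\n")
        grid = grid_from_yaml(path)
        assert grid["logistic"] == [{"solver": "lbfgs", "penalty": "l2"}]
        assert grid["tree"][0]["max_depth"] == 5

    def test_unknown_family_rejected(self, tmp_path):
        from cogload.classification import grid_from_yaml

        path = tmp_path / "grid.yaml"
        path.write_text("random_forest:\n- {n_estimators: 10}\n")
        with pytest.raises(InvalidArgumentError, match="random_forest"):
            grid_from_yaml(path)


class TestNormalization:
    def test_per_participant_z_centres_and_scales(self):
        table = make_feature_table(n_participants=3, seed=1)
        out = normalize_features(table, "per_participant_z")
        for _, block in out.groupby("participant"):
            for col in ("f0", "f1"):
                assert abs(block[col].mean()) < 1e-9
                assert block[col].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_constant_column_becomes_zero_without_error(self):
        table = make_feature_table(n_participants=2, seed=2)
        table["f0"] = 5.0
        out = normalize_features(table, "per_participant_z")
        np.testing.assert_allclose(out["f0"], 0.0)

    def test_unknown_stage_rejected(self):
        with pytest.raises(InvalidArgumentError):
            normalize_features(make_feature_table(), "global_z")

    def test_minmax_clips_test_rows_to_unit_interval(self):
        train = pd.DataFrame({"x": [0.0, 10.0]})
        scaler = fit_minmax(train)
        z = apply_minmax(scaler, pd.DataFrame({"x": [5.0, 20.0, -3.0]}),
                         clip=True)
        np.testing.assert_allclose(z[:, 0], [0.5, 1.0, 0.0])

    def test_minmax_imputes_with_train_medians(self):
        train = pd.DataFrame({"x": [0.0, 5.0, 10.0]})
        scaler = fit_minmax(train)
        z = apply_minmax(scaler, pd.DataFrame({"x": [np.nan]}), clip=True)
        assert z[0, 0] == pytest.approx(0.5)


class TestWeightedF1:
    def test_perfect_predictions_score_one(self):
        assert weighted_f1([0, 1, 1], [0, 1, 1]) == 1.0

    def test_all_positive_on_imbalanced_truth(self):
        """3 positives, 1 negative, predict all positive:
        F1+ = 6/7 weighted 0.75, F1- = 0 weighted 0.25."""
        score = weighted_f1([1, 1, 1, 1], [1, 1, 1, 0])
        assert score == pytest.approx(0.75 * (6 / 7), abs=1e-12)

    @settings(deadline=None, max_examples=200)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 5))
    def test_agrees_with_sklearn_confusion_matrix_oracle(self, seed, k):
        from sklearn.metrics import f1_score

        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 60))
        y_true = rng.integers(0, k, n)
        y_pred = rng.integers(0, k, n)
        ours = weighted_f1(y_pred, y_true)
        theirs = f1_score(y_true, y_pred, average="weighted",
                          labels=np.unique(y_true), zero_division=0)
        assert ours == pytest.approx(theirs, abs=1e-12)
        assert 0.0 <= ours <= 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidArgumentError):
            weighted_f1([], [])
        with pytest.raises(InvalidArgumentError):
            accuracy([], [])


class TestLooCV:
    def test_one_fold_per_participant(self):
        table = make_feature_table(n_participants=5, separation=3.0)
        rep = loo_cv(table, [LOGISTIC], PROBLEM2, _spec(table), seed=0)
        assert sorted(rep.rows["fold"]) == sorted(table["participant"].unique())
        assert len(rep.rows) == 5

    def test_separable_features_reach_high_f1(self):
        table = make_feature_table(n_participants=5, separation=4.0, seed=4)
        rep = loo_cv(table, [LOGISTIC], PROBLEM2, _spec(table), seed=0)
        assert rep.aggregate()["mean"].iloc[0] >= 0.9

    def test_null_features_stay_inside_permutation_band(self):
        table = make_feature_table(n_participants=4, separation=0.0, seed=5)
        rep = loo_cv(table, [LOGISTIC], PROBLEM2, _spec(table), seed=0)
        observed = rep.aggregate()["mean"].iloc[0]
        null = permutation_null(table, LOGISTIC, PROBLEM2, _spec(table),
                                n_permutations=30, seed=1)
        lo, hi = np.percentile(null, [2.5, 97.5])
        assert lo <= observed <= hi

    def test_no_leakage_from_test_only_label_feature(self):
        """A feature equal to the label on held-out rows only (noise on
        training rows) must not lift the score above chance."""
        table = make_feature_table(n_participants=4, separation=0.0, seed=6)
        rng = np.random.default_rng(0)
        probe = rng.standard_normal(len(table))
        last = table["participant"] == "P03"
        probe[last.to_numpy()] = (table.loc[last, "workload_response"] == 5)
        table["probe"] = probe
        rep = loo_cv(table, [LOGISTIC], PROBLEM2, _spec(table), seed=0)
        fold = rep.rows[rep.rows["fold"] == "P03"]
        assert fold["weighted_f1"].iloc[0] <= 0.75

    def test_min_mean_max_ordering(self):
        table = make_feature_table(n_participants=4, separation=2.0, seed=7)
        rep = loo_cv(table, [LOGISTIC], PROBLEM2, _spec(table), seed=0)
        agg = rep.aggregate()
        assert (agg["min"] <= agg["mean"]).all()
        assert (agg["mean"] <= agg["max"]).all()

    def test_single_participant_rejected(self):
        table = make_feature_table(n_participants=1)
        with pytest.raises(InvalidArgumentError):
            loo_cv(table, [LOGISTIC], PROBLEM2, _spec(table))

    def test_fold_internal_selection_finds_the_informative_feature(self):
        """Top-1 Spearman selection inside each training fold isolates the
        separable feature from the noise columns and keeps the score high."""
        table = make_feature_table(n_participants=4, n_features=10,
                                   separation=4.0, seed=21)
        rep = loo_cv(table, [LOGISTIC], PROBLEM2, _spec(table), seed=0,
                     select_top_k=1)
        assert rep.aggregate()["mean"].iloc[0] >= 0.9
        assert rep.meta["select_top_k"] == 1

    def test_degenerate_folds_are_flagged(self):
        table = make_feature_table(n_participants=3, seed=8)
        # participant P00 holds every high-load window: training folds for
        # the others keep both classes, P00's own training fold loses one
        table.loc[(table["participant"] != "P00")
                  & (table["workload_response"] == 5),
                  "workload_response"] = 1
        rep = loo_cv(table, [LOGISTIC], PROBLEM2, _spec(table), seed=0)
        assert rep.rows.set_index("fold")["degenerate"]["P00"]


class TestPersonalCV:
    def test_five_folds_per_participant(self):
        table = make_feature_table(n_participants=3, windows_per_participant=30,
                                   separation=3.0, seed=9)
        rep = personal_cv(table, [LOGISTIC], PROBLEM2, _spec(table), k=5, seed=0)
        per_part = rep.rows["fold"].str.split("/").str[0].value_counts()
        assert (per_part == 5).all()

    def test_k_equals_windows_gives_leave_one_out(self):
        table = make_feature_table(n_participants=2, windows_per_participant=8,
                                   separation=3.0, seed=10)
        rep = personal_cv(table, [LOGISTIC], PROBLEM2, _spec(table), k=8, seed=0)
        assert (rep.rows["n_test"] == 1).all()

    def test_fold_assignment_deterministic_under_seed(self):
        table = make_feature_table(n_participants=2, windows_per_participant=20,
                                   separation=1.0, seed=11)
        a = personal_cv(table, [LOGISTIC], PROBLEM2, _spec(table), seed=3)
        b = personal_cv(table, [LOGISTIC], PROBLEM2, _spec(table), seed=3)
        pd.testing.assert_frame_equal(a.rows, b.rows)

    def test_activity_features_are_null_context_when_labels_ignore_them(self):
        """With activity-independent labels the one-hot activity context
        changes mean F1 by < 0.05 (20 seeds)."""
        diffs = []
        for seed in range(20):
            table = make_feature_table(n_participants=2,
                                       windows_per_participant=60,
                                       separation=4.0, seed=seed)
            on = personal_cv(table, [LOGISTIC], PROBLEM2, _spec(table),
                             with_activity=True, seed=0)
            off = personal_cv(table, [LOGISTIC], PROBLEM2, _spec(table),
                              with_activity=False, seed=0)
            diffs.append(on.aggregate()["mean"].iloc[0]
                         - off.aggregate()["mean"].iloc[0])
        assert abs(np.mean(diffs)) < 0.05

    def test_too_small_participants_are_skipped(self, caplog):
        table = make_feature_table(n_participants=2, windows_per_participant=4,
                                   seed=12)
        big = make_feature_table(n_participants=2, windows_per_participant=30,
                                 seed=13)
        big["participant"] = big["participant"].map(
            {"P00": "P10", "P01": "P11"})
        rep = personal_cv(pd.concat([table, big], ignore_index=True),
                          [LOGISTIC], PROBLEM2, _spec(table), k=5, seed=0)
        folds = set(rep.rows["fold"].str.split("/").str[0])
        assert folds == {"P10", "P11"}


class TestReporting:
    def test_best_configuration_by_mean_f1(self):
        table = make_feature_table(n_participants=4, separation=4.0, seed=14)
        grid = [LOGISTIC, ("tree", {"criterion": "gini", "splitter": "best",
                                    "max_depth": 5})]
        rep = loo_cv(table, grid, PROBLEM2, _spec(table), seed=0)
        family, params, stats = rep.best()
        agg = rep.aggregate()
        assert stats["mean"] == pytest.approx(agg["mean"].max())
        assert family in {"logistic", "tree"}

    def test_summary_round_trips_through_json(self, tmp_path):
        table = make_feature_table(n_participants=3, separation=2.0, seed=15)
        rep = loo_cv(table, [LOGISTIC], PROBLEM2, _spec(table), seed=0)
        rep.to_json(tmp_path / "rep.json")
        back = CVReport.from_json(tmp_path / "rep.json")
        pd.testing.assert_frame_equal(back.rows, rep.rows)
        summary = write_report([rep], tmp_path / "summary")
        assert (tmp_path / "summary.json").exists()
        assert (tmp_path / "summary.csv").exists()
        loaded = json.loads((tmp_path / "summary.json").read_text())
        assert loaded[0]["mean"] == pytest.approx(summary["mean"].iloc[0])

    def test_summary_rows_scale_with_reports(self, tmp_path):
        reports = []
        for n_classes, seed in ((2, 16), (3, 17)):
            table = make_feature_table(n_participants=3, separation=2.0,
                                       seed=seed)
            reports.append(loo_cv(table, [LOGISTIC],
                                  ClassificationProblem(n_classes),
                                  _spec(table), seed=0))
        summary = write_report(reports, tmp_path / "s")
        assert len(summary) == 2
        assert (summary["min"] <= summary["mean"]).all()
        assert (summary["mean"] <= summary["max"]).all()
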