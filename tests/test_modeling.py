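"""Subject-wise splitting, LOOCV search, importance and ablation."""

import numpy as np
import pytest

from armfatigue.features import canonical_feature_names
from armfatigue.modeling import (DEFAULT_TOP_K, SENSOR_COMBOS, ModelSpec,
                                 ablate_sensors, loocv_grid_search,
                                 make_estimator, rank_importance,
                                 select_top_features, split_dataset,
                                 train_test_counts)


class TestSplitArithmetic:
    @pytest.mark.parametrize("n, ratio, expected", [
        (1240, 0.70, (868, 372)),
        (30, 0.70, (21, 9)),
        (10, 0.70, (7, 3)),
    ])
    def test_counts(self, n, ratio, expected):
        assert train_test_counts(n, ratio) == expected

    def test_ratio_bounds(self):
        for ratio in (0.0, 1.0, -0.2, 1.4):
            with pytest.raises(ValueError):
                train_test_counts(10, ratio)


class TestSplitDataset:
    ids = [f"S{i:02d}" for i in range(1, 31)]

    def test_subject_partition(self):
        plan = split_dataset(self.ids, seed=4)
        assert len(plan.train_subjects) == 21
        assert len(plan.test_subjects) == 9
        assert set(plan.train_subjects) | set(plan.test_subjects) \
            == set(self.ids)
        assert not set(plan.train_subjects) & set(plan.test_subjects)

    def test_deterministic(self):
        a = split_dataset(self.ids, seed=4)
        b = split_dataset(self.ids, seed=4)
        assert a.train_subjects == b.train_subjects
        assert a.test_subjects == b.test_subjects

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            split_dataset(["only"], seed=0)


class TestLoocvGridSearch:
    def test_fold_count_equals_train_subjects(self, fake_feature_table):
        cols = canonical_feature_names()
        plan = split_dataset(fake_feature_table["subject_id"], seed=2)
        spec = ModelSpec(family="dt")
        res = loocv_grid_search(fake_feature_table, cols, plan, spec, seed=2)
        assert res.n_folds == len(plan.train_subjects) == 21
        assert (res.cv_table["n_folds"] == 21).all()

    def test_singleton_grid_returned(self, fake_feature_table):
        cols = canonical_feature_names()
        plan = split_dataset(fake_feature_table["subject_id"], seed=2)
        spec = ModelSpec(family="dt",
                         grid={"criterion": ["entropy"],
                               "min_samples_leaf": [2]})
        res = loocv_grid_search(fake_feature_table, cols, plan, spec, seed=2)
        assert res.best_params == {"criterion": "entropy",
                                   "min_samples_leaf": 2}
        assert len(res.cv_table) == 1

    def test_deterministic_selection(self, fake_feature_table):
        cols = canonical_feature_names()
        plan = split_dataset(fake_feature_table["subject_id"], seed=2)
        spec = ModelSpec(family="dt",
                         grid={"min_samples_leaf": [1, 4]})
        r1 = loocv_grid_search(fake_feature_table, cols, plan, spec, seed=2)
        r2 = loocv_grid_search(fake_feature_table, cols, plan, spec, seed=2)
        assert r1.best_params == r2.best_params
        assert r1.cv_table.equals(r2.cv_table)


class TestRankImportance:
    def _fitted(self, table, cols, constant=None):
        X = table[cols].copy()
        if constant is not None:
            X[constant] = 1.0
        model = make_estimator("lgbm", {"n_estimators": 20,
                                        "num_leaves": 15}, seed=0)
        model.fit(X, table["state"])
        return model

    def test_counts_match_bruteforce_tree_traversal(self, fake_feature_table):
        cols = canonical_feature_names()
        model = self._fitted(fake_feature_table, cols)
        ranking = rank_importance(model, cols)
        # oracle: walk every tree of the dumped booster, counting splits
        def count_splits(node, counter):
            if "split_feature" in node:
                counter[node["split_feature"]] += 1
                count_splits(node["left_child"], counter)
                count_splits(node["right_child"], counter)
        counter = {i: 0 for i in range(len(cols))}
        for tree in model.booster_.dump_model()["tree_info"]:
            count_splits(tree["tree_structure"], counter)
        oracle = {cols[i]: n for i, n in counter.items()}
        assert dict(ranking) == oracle
        assert sum(n for _, n in ranking) == sum(oracle.values()) > 0

    def test_constant_feature_unused(self, fake_feature_table):
        cols = canonical_feature_names()
        model = self._fitted(fake_feature_table, cols,
                             constant="IMU1_AccZ_amp")
        ranking = dict(rank_importance(model, cols))
        assert ranking["IMU1_AccZ_amp"] == 0

    def test_ranking_is_permutation_sorted(self, fake_feature_table):
        cols = canonical_feature_names()
        model = self._fitted(fake_feature_table, cols)
        ranking = rank_importance(model, cols)
        assert sorted(n for n, _ in ranking) == sorted(cols)
        counts = [c for _, c in ranking]
        assert counts == sorted(counts, reverse=True)

    def test_non_tree_model_rejected(self):
        from sklearn.tree import DecisionTreeClassifier
        with pytest.raises(TypeError):
            rank_importance(DecisionTreeClassifier(), ["a"])


class TestSelectTopFeatures:
    ranking = [("a", 5), ("b", 3), ("c", 1), ("d", 0)]

    def test_prefix_nesting(self):
        tops = [select_top_features(self.ranking, k) for k in (1, 2, 3, 4)]
        for small, big in zip(tops, tops[1:]):
            assert set(small) < set(big)
        assert tops[-1] == ["a", "b", "c", "d"]

    def test_k_bounds(self):
        for k in (0, 5):
            with pytest.raises(ValueError):
                select_top_features(self.ranking, k)


class TestAblation:
    def test_combo_feature_budgets(self):
        assert len(canonical_feature_names(SENSOR_COMBOS["emg"])) == 7
        assert len(canonical_feature_names(SENSOR_COMBOS["imus+ofs"])) == 56
        assert DEFAULT_TOP_K["imus+ofs"] == 13

    def test_oversized_k_rejected(self, fake_feature_table):
        plan = split_dataset(fake_feature_table["subject_id"], seed=2)
        with pytest.raises(ValueError):
            ablate_sensors(fake_feature_table, plan,
                           {"n_estimators": 10}, combos=["emg"],
                           top_k={"emg": 8}, seed=2)

    def test_reports_per_combo(self, fake_feature_table):
        plan = split_dataset(fake_feature_table["subject_id"], seed=2)
        reports = ablate_sensors(fake_feature_table, plan,
                                 {"n_estimators": 10, "num_leaves": 15},
                                 combos=["emg", "imus"], seed=2)
        assert set(reports) == {"emg", "imus"}
        emg = reports["emg"]
        assert emg["metadata"]["n_features"] == 7
        assert len(emg["features"]) == 7
        assert int(np.sum(emg["confusion_matrix"])) == emg["n_test_cycles"]
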