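"""Feature selection, balanced undersampling instances, SVM protocol."""

import numpy as np
import pandas as pd
import pytest

from conncog.classify import (
    ClassifyError,
    FeatureSelectionError,
    aggregate_performance,
    build_instances,
    default_c_grid,
    default_gamma_grid,
    feature_weights,
    grid_search_svm,
    run_cv,
    select_features,
)

SMALL_C = [2.0**e for e in (-1, 3, 7)]
SMALL_GAMMA = [2.0**e for e in (-9, -5, -1)]


def _stats_df(sig_nodes_by_metric, n_nodes=10):
    rows = []
    for metric in ("local_efficiency", "strength"):
        sig = sig_nodes_by_metric.get(metric, {})
        for contrast in ("CP-HV", "CI-CP"):
            for j in range(n_nodes):
                node = f"node{j:03d}"
                is_sig = j in sig.get(contrast, set())
                rows.append({
                    "metric": metric, "node": node, "contrast": contrast,
                    "raw_p": 0.001 if is_sig else 0.5,
                    "corrected_p": 0.01 if is_sig else 0.9,
                    "direction": -1 if is_sig else 0,
                })
    return pd.DataFrame(rows)


def _subjects(n_hv=45, n_cp=104, n_ci=84):
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n_hv + n_cp + n_ci)],
        "group": ["HV"] * n_hv + ["CP"] * n_cp + ["CI"] * n_ci,
    })


class TestSelectFeatures:
    def test_nodes_significant_in_both_contrasts_only(self):
        stats = _stats_df({
            "local_efficiency": {"CP-HV": {3, 7, 9}, "CI-CP": {3, 7, 5}},
        })
        got = select_features(stats, "LE")
        assert got == [("local_efficiency", "node003"),
                       ("local_efficiency", "node007")]

    def test_empty_selection_raises(self):
        with pytest.raises(FeatureSelectionError, match="relax"):
            select_features(_stats_df({}), "LE")

    def test_union_feature_set_counts_add(self):
        stats = _stats_df({
            "local_efficiency": {"CP-HV": {1, 2}, "CI-CP": {1, 2}},
            "strength": {"CP-HV": {2, 4, 6}, "CI-CP": {2, 4, 6}},
        })
        le = select_features(stats, "LE")
        ns = select_features(stats, "NS")
        both = select_features(stats, "LE+NS")
        assert len(both) == len(le) + len(ns) == 5


class TestBuildInstances:
    def test_paper_sized_ms_vs_hv_composition(self):
        subjects = _subjects()
        instances = build_instances(subjects, "ms_vs_hv", n_instances=10,
                                    seed=1)
        for idx in instances:
            sub = subjects.loc[idx]
            counts = sub["group"].value_counts()
            assert len(sub) == 90
            assert counts["HV"] == 45
            assert counts["CP"] == 25
            assert counts["CI"] == 20
            assert sub["subject_id"].is_unique

    def test_paper_sized_ci_vs_cp_composition(self):
        subjects = _subjects()
        for idx in build_instances(subjects, "ci_vs_cp", n_instances=5,
                                   seed=2):
            counts = subjects.loc[idx]["group"].value_counts()
            assert counts["CI"] == 84
            assert counts["CP"] == 84
            assert counts.get("HV", 0) == 0

    def test_already_balanced_uses_full_data(self):
        subjects = _subjects(n_hv=0, n_cp=30, n_ci=30)
        for idx in build_instances(subjects, "ci_vs_cp", n_instances=3,
                                   seed=3):
            assert len(idx) == 60

    def test_instances_differ_only_in_majority_subsample(self):
        subjects = _subjects(n_hv=20, n_cp=40, n_ci=30)
        instances = build_instances(subjects, "ms_vs_hv", n_instances=20,
                                    seed=4)
        hv_idx = set(subjects.index[subjects["group"] == "HV"])
        assert all(hv_idx <= set(idx) for idx in instances)
        assert len({tuple(idx) for idx in instances}) > 1

    def test_deterministic_given_seed(self):
        subjects = _subjects(n_hv=10, n_cp=30, n_ci=20)
        a = build_instances(subjects, "ms_vs_hv", n_instances=5, seed=9)
        b = build_instances(subjects, "ms_vs_hv", n_instances=5, seed=9)
        assert all(x.equals(y) for x, y in zip(a, b))

    def test_empty_class_rejected(self):
        with pytest.raises(ClassifyError):
            build_instances(_subjects(n_hv=0, n_cp=10, n_ci=10), "ms_vs_hv")


def _separable_data(rng, n_per=30, d=4, gap=6.0):
    X = np.vstack([rng.normal(0, 1, (n_per, d)),
                   rng.normal(gap, 1, (n_per, d))])
    y = np.array(["A"] * n_per + ["B"] * n_per)
    return X, y


class TestGridSearch:
    def test_separable_data_reaches_perfect_cv_accuracy(self, rng):
        X, y = _separable_data(rng)
        C, gamma = grid_search_svm(X, y, SMALL_C, SMALL_GAMMA, k=5, seed=0)
        assert C in SMALL_C and gamma in SMALL_GAMMA

    def test_deterministic(self, rng):
        X, y = _separable_data(rng, gap=1.0)
        a = grid_search_svm(X, y, SMALL_C, SMALL_GAMMA, k=5, seed=3)
        b = grid_search_svm(X, y, SMALL_C, SMALL_GAMMA, k=5, seed=3)
        assert a == b

    def test_tie_break_prefers_small_c_then_gamma(self, rng):
        # perfectly separable: many grid points tie at 100% accuracy and the
        # smallest (C, gamma) achieving the maximum must win
        X, y = _separable_data(rng, gap=20.0)
        C, gamma = grid_search_svm(X, y, SMALL_C, SMALL_GAMMA, k=5, seed=0)
        accs = {}
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(5, shuffle=True, random_state=0)
        for c in SMALL_C:
            for g in SMALL_GAMMA:
                hits = tot = 0
                for tr, te in skf.split(X, y):
                    sc = StandardScaler().fit(X[tr])
                    clf = SVC(C=c, gamma=g).fit(sc.transform(X[tr]), y[tr])
                    hits += (clf.predict(sc.transform(X[te])) == y[te]).sum()
                    tot += len(te)
                accs[(c, g)] = hits / tot
        best_acc = max(accs.values())
        expected = min(k for k, v in accs.items() if v == best_acc)
        assert (C, gamma) == expected

    def test_single_class_rejected(self, rng):
        X = rng.normal(0, 1, (20, 3))
        with pytest.raises(ClassifyError):
            grid_search_svm(X, np.array(["A"] * 20), SMALL_C, SMALL_GAMMA)

    def test_permuted_labels_near_chance(self, rng):
        X = rng.normal(0, 1, (60, 5))
        y = np.array(["A", "B"] * 30)
        accs = []
        from sklearn.model_selection import StratifiedKFold
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        for rep in range(5):
            yp = rng.permutation(y)
            C, gamma = grid_search_svm(X, yp, SMALL_C, SMALL_GAMMA, k=5,
                                       seed=rep)
            skf = StratifiedKFold(5, shuffle=True, random_state=100 + rep)
            hits = tot = 0
            for tr, te in skf.split(X, yp):
                sc = StandardScaler().fit(X[tr])
                clf = SVC(C=C, gamma=gamma).fit(sc.transform(X[tr]), yp[tr])
                hits += (clf.predict(sc.transform(X[te])) == yp[te]).sum()
                tot += len(te)
            accs.append(hits / tot)
        assert 0.3 < np.mean(accs) < 0.7

    def test_default_grids_are_growing_dyadic_sequences(self):
        c = default_c_grid()
        g = default_gamma_grid()
        assert c[0] == 2.0**-5 and c[-1] == 2.0**15 and len(c) == 11
        assert g[0] == 2.0**-15 and g[-1] == 2.0**3 and len(g) == 10
        assert np.all(np.diff(c) > 0) and np.all(np.diff(g) > 0)


class TestRunCV:
    def test_fold_sizes_81_train_9_test_on_90(self, rng):
        X = rng.normal(0, 1, (90, 4))
        y = np.array(["MS"] * 45 + ["HV"] * 45)
        from sklearn.model_selection import StratifiedKFold

        for tr, te in StratifiedKFold(10, shuffle=True,
                                      random_state=0).split(X, y):
            assert len(tr) == 81 and len(te) == 9

    def test_separable_instance_reaches_100(self, rng):
        X, y = _separable_data(rng, n_per=25, gap=8.0)
        res = run_cv(X, y, positive_class="B", k=5, seed=0,
                     C_grid=SMALL_C, gamma_grid=SMALL_GAMMA, inner_k=3)
        assert res.accuracy == 100.0
        assert res.sensitivity == 100.0
        assert res.f1 == 100.0

    def test_confusion_counts_consistent_with_indicators(self, rng):
        X, y = _separable_data(rng, n_per=20, gap=1.0)
        res = run_cv(X, y, positive_class="B", k=4, seed=1,
                     C_grid=SMALL_C, gamma_grid=SMALL_GAMMA, inner_k=3)
        tp, fp, tn, fn = res.confusion
        assert tp + fp + tn + fn == 40
        assert res.accuracy == pytest.approx(100 * (tp + tn) / 40)
        assert res.f1 == pytest.approx(100 * 2 * tp / (2 * tp + fp + fn))

    def test_deterministic_given_seed(self, rng):
        X, y = _separable_data(rng, n_per=20, gap=1.0)
        r1 = run_cv(X, y, "B", k=4, seed=5, C_grid=SMALL_C,
                    gamma_grid=SMALL_GAMMA, inner_k=3)
        r2 = run_cv(X, y, "B", k=4, seed=5, C_grid=SMALL_C,
                    gamma_grid=SMALL_GAMMA, inner_k=3)
        assert r1.confusion == r2.confusion
        assert r1.fold_params == r2.fold_params


class TestLeakageCanary:
    def test_test_fold_rows_do_not_shape_training(self, rng):
        # Corrupt the rows of one held-out fold wildly: the per-fold scaler
        # statistics and grid-searched (C, gamma) of every fold must be
        # unchanged, because both may only depend on training folds.
        X, y = _separable_data(rng, n_per=20, gap=1.0)
        from sklearn.model_selection import StratifiedKFold

        folds = list(StratifiedKFold(4, shuffle=True,
                                     random_state=5).split(X, y))
        te0 = folds[0][1]
        X_corrupt = X.copy()
        X_corrupt[te0] *= 1000.0
        base = run_cv(X, y, "B", k=4, seed=5, C_grid=SMALL_C,
                      gamma_grid=SMALL_GAMMA, inner_k=3)
        pert = run_cv(X_corrupt, y, "B", k=4, seed=5, C_grid=SMALL_C,
                      gamma_grid=SMALL_GAMMA, inner_k=3)
        assert base.fold_params[0] == pert.fold_params[0]
        np.testing.assert_array_equal(base.fold_scaler_means[0],
                                      pert.fold_scaler_means[0])


class TestAggregateAndWeights:
    def _result(self, acc):
        from conncog.classify import InstanceResult

        r = InstanceResult(0, [])
        r.accuracy = r.sensitivity = r.specificity = r.f1 = acc
        return r

    def test_identical_instances_zero_sd(self):
        s = aggregate_performance([self._result(80.0)] * 5)
        assert s.sd["accuracy"] == 0.0

    def test_two_instance_hand_arithmetic(self):
        s = aggregate_performance([self._result(70.0), self._result(80.0)])
        assert s.mean["accuracy"] == pytest.approx(75.0)
        assert s.sd["accuracy"] == pytest.approx(np.sqrt(50.0))  # ~7.07

    def test_empty_rejected(self):
        with pytest.raises(ClassifyError):
            aggregate_performance([])

    def test_planted_informative_feature_ranks_first(self, rng):
        features = [("strength", f"node{j:03d}") for j in range(6)]
        data = []
        for _ in range(10):
            y = np.array(["A"] * 30 + ["B"] * 30)
            X = rng.normal(0, 1, (60, 6))
            X[y == "B", 2] += 4.0  # only feature 2 is informative
            data.append((X, y))
        ranking = feature_weights(data, features, top_k=6)
        assert ranking.iloc[0]["node"] == "node002"
        assert (ranking["sd_weight"] >= 0).all()

    def test_fewer_features_than_top_k_warns(self, rng):
        features = [("strength", "node000"), ("strength", "node001")]
        y = np.array(["A"] * 10 + ["B"] * 10)
        data = [(rng.normal(0, 1, (20, 2)), y)]
        with pytest.warns(UserWarning, match="only 2"):
            out = feature_weights(data, features, top_k=15)
        assert len(out) == 2
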