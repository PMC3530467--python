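import math

import numpy as np
import pandas as pd
import pytest

from netmark import classify
from netmark.classify import ActivityMatrix
from netmark.io import OmicsMatrix
from netmark.search import Module

from conftest import make_matrix


def activity_matrix(X, labels, features=None, samples=None):
    samples = samples or [f"s{i}" for i in range(len(X))]
    features = features or [f"f{j}" for j in range(np.shape(X)[1])]
    values = pd.DataFrame(np.asarray(X, float), index=samples, columns=features)
    return ActivityMatrix(values, pd.Series(labels, index=samples))


class TestTrainingExtremes:
    def test_hand_selection(self):
        surv = pd.Series([0.1, 0.2, 3.0, 4.0], index=["a", "b", "c", "d"])
        longs, shorts = classify.select_training_extremes(surv, k=2)
        assert set(longs) == {"c", "d"} and set(shorts) == {"a", "b"}
        assert longs[0] == "d"  # longest first

    def test_insufficient_pool_errors(self):
        surv = pd.Series([0.1, 3.0, 4.0], index=["a", "c", "d"])
        with pytest.raises(ValueError, match="2"):
            classify.select_training_extremes(surv, k=2)

    def test_tie_broken_by_sample_id(self):
        surv = pd.Series([3.0, 3.0, 3.0, 0.1, 0.2], index=["z", "a", "m", "q", "r"])
        longs, _ = classify.select_training_extremes(surv, k=2, lower=0.5)
        assert longs == ["a", "m"]


class TestZscore:
    def test_hand_row(self):
        m = make_matrix([[1, 2, 3]], ["g1"], ["a", "b", "c"])
        z, flags = classify.zscore_normalize(m)
        np.testing.assert_allclose(z.loc["g1"], [-1.0, 0.0, 1.0])
        assert flags == []

    def test_constant_row_flagged(self):
        m = make_matrix([[5, 5, 5], [1, 2, 3]], ["g1", "g2"], ["a", "b", "c"])
        z, flags = classify.zscore_normalize(m)
        np.testing.assert_allclose(z.loc["g1"], 0.0)
        assert flags == ["g1"]

    def test_rows_standardised(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(size=(20, 15)),
                        [f"g{i}" for i in range(20)], [f"s{j}" for j in range(15)])
        z, _ = classify.zscore_normalize(m)
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0, rtol=1e-12)

    def test_single_sample_errors(self):
        m = make_matrix([[1.0]], ["g1"], ["a"])
        with pytest.raises(ValueError):
            classify.zscore_normalize(m)


class TestModuleActivity:
    def _z(self):
        return pd.DataFrame(
            [[1.0, 0.0], [4.0, 0.0], [1.0, 0.0]],
            index=["A", "B", "C"], columns=["s1", "s2"],
        )

    def test_hand_value_two_genes(self):
        mod = Module(frozenset({"A", "B"}), "expression")
        a = classify.module_activity(mod, self._z(), "s1")
        assert a == pytest.approx(5.0 / math.sqrt(2))

    def test_zero_profile(self):
        mod = Module(frozenset({"A", "B"}), "expression")
        assert classify.module_activity(mod, self._z(), "s2") == 0.0

    def test_sqrt_three(self):
        mod = Module(frozenset({"A", "B", "C"}), "expression")
        z = self._z()
        z.loc["B", "s1"] = 1.0
        assert classify.module_activity(mod, z, "s1") == pytest.approx(math.sqrt(3))

    def test_linear_in_z(self):
        mod = Module(frozenset({"A", "B"}), "expression")
        z = self._z()
        a1 = classify.module_activity(mod, z, "s1")
        a2 = classify.module_activity(mod, 2.5 * z, "s1")
        assert a2 == pytest.approx(2.5 * a1)

    def test_absent_genes_error(self):
        mod = Module(frozenset({"X"}), "expression")
        with pytest.raises(ValueError):
            classify.module_activity(mod, self._z(), "s1")


class TestBuildFeatureMatrix:
    def _setup(self, n_modules=13):
        rng = np.random.default_rng(0)
        genes = [f"g{i:03d}" for i in range(n_modules * 3)]
        samples = [f"s{j}" for j in range(8)]
        z = pd.DataFrame(rng.normal(size=(len(genes), 8)), index=genes,
                         columns=samples)
        mods = [
            Module(frozenset(genes[3 * i:3 * i + 3]), "expression",
                   name=f"mod{i:02d}")
            for i in range(n_modules)
        ]
        labels = pd.Series(["positive"] * 4 + ["negative"] * 4, index=samples)
        return mods, z, samples, labels

    def test_combined_mode_doubles_columns(self):
        mods, z, samples, labels = self._setup(13)
        am = classify.build_feature_matrix(mods, z, z.copy(), samples, labels)
        assert len(am.features) == 26

    def test_missing_analyte_column_omitted(self, caplog):
        mods, z, samples, labels = self._setup(2)
        meth = z.drop(index=list(mods[0].genes))
        with caplog.at_level("WARNING"):
            am = classify.build_feature_matrix(mods, z, meth, samples, labels)
        assert len(am.features) == 3

    def test_single_analyte_mode(self):
        mods, z, samples, labels = self._setup(4)
        am = classify.build_feature_matrix(mods, z, None, samples, labels,
                                           mode="expression")
        assert len(am.features) == 4


class TestTrainSvm:
    def test_separable_toy(self):
        X = [[0, 0], [0.2, 0], [5, 5], [5.3, 4.8]]
        am = activity_matrix(X, ["negative", "negative", "positive", "positive"])
        clf = classify.train_svm(am)
        Xv, y = am.xy()
        assert (clf.predict(Xv) == y).all()

    def test_xor_quadratic_separates_linear_cannot(self):
        X = [[1, 1], [-1, -1], [1, -1], [-1, 1]] * 4
        labels = (["positive", "positive", "negative", "negative"] * 4)
        rng = np.random.default_rng(0)
        X = np.array(X, float) + 0.05 * rng.standard_normal((16, 2))
        am = activity_matrix(X, labels)
        Xv, y = am.xy()
        quad = classify.train_svm(am, kernel="quadratic")
        lin = classify.train_svm(am, kernel="linear")
        assert (quad.predict(Xv) == y).all()
        assert (lin.predict(Xv) == y).mean() < 1.0

    def test_row_duplication_leaves_predictions_unchanged(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 3))
        y = ["positive" if x[0] + 0.3 * x[1] > 0 else "negative" for x in X]
        am1 = activity_matrix(X, y)
        am2 = activity_matrix(
            np.vstack([X, X]), y + y,
            samples=[f"s{i}" for i in range(24)],
        )
        grid = rng.normal(size=(40, 3))
        c1 = classify.train_svm(am1)
        c2 = classify.train_svm(am2)
        assert (c1.predict(grid) == c2.predict(grid)).all()

    def test_single_class_errors(self):
        am = activity_matrix([[1, 2], [3, 4]], ["positive", "positive"])
        with pytest.raises(ValueError):
            classify.train_svm(am)


class TestRfe:
    def test_single_feature_selected(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(2, 1, 10), rng.normal(-2, 1, 10)])
        am = activity_matrix(x[:, None], ["positive"] * 10 + ["negative"] * 10,
                             samples=[f"s{i}" for i in range(20)])
        subset, path, elim = classify.rfe_select(am)
        assert subset == ["f0"] and elim == [] and len(path) == 1

    def test_loop_contract(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 6))
        X[:10, 0] += 3
        am = activity_matrix(X, ["positive"] * 10 + ["negative"] * 10,
                             samples=[f"s{i}" for i in range(20)])
        subset, path, elim = classify.rfe_select(am)
        assert len(path) == 6  # one accuracy entry per subset size
        assert [n for n, _ in path] == [6, 5, 4, 3, 2, 1]
        assert len(elim) == 5
        best_acc = max(a for _, a in path)
        assert any(a == best_acc and n == len(subset) for n, a in path)

    def test_informative_features_survive(self):
        # 5 complementary informative features (each detects a disjoint
        # fifth of the positives, so none is redundant) + 20 pure-noise
        # features: all informative ones reach the selected subset in
        # >= 90% of seeded runs
        wins = 0
        n_runs = 10
        for seed in range(n_runs):
            rng = np.random.default_rng(700 + seed)
            X = rng.normal(size=(40, 25))
            for j in range(5):
                X[4 * j:4 * j + 4, j] += 8.0
            am = activity_matrix(
                X, ["positive"] * 20 + ["negative"] * 20,
                samples=[f"s{i}" for i in range(40)],
            )
            subset, _, _ = classify.rfe_select(am)
            wins += all(f"f{j}" in subset for j in range(5))
        assert wins >= 0.9 * n_runs


class TestPairedLoocv:
    def _features(self, n_pos, n_pool, informative=True, seed=0):
        rng = np.random.default_rng(seed)
        n = n_pos + n_pool
        if informative:
            # wide-margin single informative dimension, negligible noise
            X = 0.05 * rng.normal(size=(n, 3))
            X[:n_pos, 0] += 10.0
        else:
            X = rng.normal(size=(n, 3))
        labels = ["positive"] * n_pos + ["negative"] * n_pool
        samples = [f"p{i}" for i in range(n_pos)] + [f"n{i}" for i in range(n_pool)]
        return activity_matrix(X, labels, samples=samples), samples[:n_pos], samples[n_pos:]

    def test_separable_features_reach_perfect_accuracy(self):
        am, pos, pool = self._features(8, 12)
        mean, sd, accs = classify.paired_loocv(am, pos, pool, n_repeats=5, seed=1)
        assert mean == 1.0 and sd == 0.0 and len(accs) == 5

    def test_accuracies_are_valid_fold_fractions(self):
        am, pos, pool = self._features(6, 9, informative=False, seed=2)
        mean, _, accs = classify.paired_loocv(am, pos, pool, n_repeats=8, seed=3)
        k = len(pos)
        for a in accs:
            assert 0.0 <= a <= 1.0
            assert round(a * 2 * k) == pytest.approx(a * 2 * k)  # counts of 2k tests

    def test_pool_too_small_errors(self):
        am, pos, pool = self._features(8, 5)
        with pytest.raises(ValueError, match="pool"):
            classify.paired_loocv(am, pos, pool, n_repeats=2, seed=0)

    def test_label_randomized_features_near_chance(self):
        # criterion-style null: uninformative features, 21+21 design
        rng = np.random.default_rng(11)
        n_pos, n_pool = 21, 40
        X = rng.normal(size=(n_pos + n_pool, 6))
        samples = [f"p{i}" for i in range(n_pos)] + [f"n{i}" for i in range(n_pool)]
        am = activity_matrix(X, ["positive"] * n_pos + ["negative"] * n_pool,
                             samples=samples)
        mean, _, _ = classify.paired_loocv(am, samples[:n_pos], samples[n_pos:],
                                           n_repeats=25, seed=5)
        assert 0.38 <= mean <= 0.62  # loose band for the quick 25-repeat check

    def test_determinism(self):
        am, pos, pool = self._features(6, 9, informative=False, seed=4)
        r1 = classify.paired_loocv(am, pos, pool, n_repeats=4, seed=9)
        r2 = classify.paired_loocv(am, pos, pool, n_repeats=4, seed=9)
        np.testing.assert_array_equal(r1[2], r2[2])


def test_top_genes_baseline_picks_most_differential():
    sig = pd.DataFrame(
        {"d": [5.0, 0.1, -4.0, 0.2], "q": [0.001, 0.9, 0.001, 0.8]},
        index=["g1", "g2", "g3", "g4"],
    )
    z = pd.DataFrame(np.eye(4), index=["g1", "g2", "g3", "g4"],
                     columns=["s1", "s2", "s3", "s4"])
    labels = pd.Series(["positive", "positive", "negative", "negative"],
                       index=["s1", "s2", "s3", "s4"])
    am = classify.top_genes_baseline(sig, z, 2, ["s1", "s2", "s3", "s4"], labels)
    assert set(am.features) == {"g1", "g3"}
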