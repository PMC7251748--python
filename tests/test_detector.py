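import numpy as np
import pytest
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.tree import DecisionTreeClassifier

import pharfric as pf
from pharfric.detector import EnsembleModel, _confusion_metrics
from pharfric.errors import ConfigError, DegenerateTrainingError, ShapeError


def make_fm(X, y, consonants=None):
    labels = np.where(np.asarray(y, bool), "PF", "NS")
    if consonants is None:
        consonants = np.array(pf.CONSONANTS)[np.arange(len(labels)) % 6]
    return pf.FeatureMatrix(np.asarray(X, float), labels,
                            np.asarray(consonants))


def separable_fm(n=60, seed=0):
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2 == 0
    X = np.where(y[:, None], rng.uniform(0.6, 1.0, (n, 3)),
                 rng.uniform(0.0, 0.4, (n, 3)))
    return make_fm(X, y)


def noise_fm(n=200, d=10, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.permutation(np.arange(n) % 2 == 0)
    return make_fm(rng.standard_normal((n, d)), y)


class TestFitBagging:
    def test_single_tree_without_bootstrap_matches_tree(self):
        fm = separable_fm()
        model = pf.fit_bagging(fm, T=1, seed=5, bootstrap=False)
        labels, _ = pf.predict(model, fm.X)
        tree = DecisionTreeClassifier(random_state=0).fit(fm.X, fm.y)
        assert np.array_equal(labels == "PF", tree.predict(fm.X))

    def test_separable_training_accuracy(self):
        fm = separable_fm()
        model = pf.fit_bagging(fm, T=30, seed=1)
        labels, _ = pf.predict(model, fm.X)
        assert np.mean((labels == "PF") == fm.y) == 1.0

    def test_same_seed_same_predictions(self):
        fm = separable_fm()
        held = np.random.default_rng(9).uniform(0, 1, (25, 3))
        m1 = pf.fit_bagging(fm, T=15, seed=42)
        m2 = pf.fit_bagging(fm, T=15, seed=42)
        l1, f1 = pf.predict(m1, held)
        l2, f2 = pf.predict(m2, held)
        assert np.array_equal(l1, l2)
        assert np.array_equal(f1, f2)

    def test_single_class_raises(self):
        fm = make_fm(np.random.default_rng(0).standard_normal((10, 2)),
                     np.ones(10, bool))
        with pytest.raises(DegenerateTrainingError):
            pf.fit_bagging(fm, T=5, seed=0)


class TestPredict:
    def test_vote_fraction_is_probability(self):
        fm = separable_fm()
        model = pf.fit_bagging(fm, T=30, seed=2)
        _, frac = pf.predict(model, np.random.default_rng(3).standard_normal((50, 3)))
        assert np.all((frac >= 0) & (frac <= 1))

    def test_unanimous_votes_hit_extremes(self):
        fm = separable_fm()
        model = pf.fit_bagging(fm, T=30, seed=2)
        _, frac = pf.predict(model, np.array([[0.9, 0.9, 0.9], [0.1, 0.1, 0.1]]))
        assert frac[0] == 1.0 and frac[1] == 0.0

    def test_tie_breaks_to_ns(self):
        X = np.array([[0.0], [1.0]])
        t_pf = DecisionTreeClassifier().fit(X, [True, True])
        t_ns = DecisionTreeClassifier().fit(X, [False, False])
        model = EnsembleModel(trees=[t_pf, t_ns], T=2, seed=None, n_features=1)
        labels, frac = pf.predict(model, np.array([[0.5]]))
        assert frac[0] == 0.5
        assert labels[0] == "NS"

    def test_dimension_mismatch(self):
        model = pf.fit_bagging(separable_fm(), T=3, seed=0)
        with pytest.raises(ShapeError):
            pf.predict(model, np.zeros((4, 7)))


class TestConfusionMetrics:
    def test_matches_sklearn_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            y = rng.integers(0, 2, 50).astype(bool)
            p = rng.integers(0, 2, 50).astype(bool)
            if len(np.unique(y)) < 2:
                continue
            m = _confusion_metrics(y, p)
            tn, fp, fn, tp = confusion_matrix(y, p).ravel()
            assert m["accuracy"] == pytest.approx(100 * (tp + tn) / 50)
            assert m["sensitivity"] == pytest.approx(100 * tp / (tp + fn))
            assert m["specificity"] == pytest.approx(100 * tn / (tn + fp))


class TestCrossValidate:
    def test_null_features_near_chance(self):
        res = pf.cross_validate(noise_fm(200), k=10, repeats=3, T=10, seed=0)
        assert 40.0 <= res.accuracy.mean <= 60.0

    def test_separable_is_perfect(self):
        res = pf.cross_validate(separable_fm(80), k=10, repeats=2, T=10, seed=0)
        assert res.accuracy.mean == 100.0
        assert res.auc.mean == 100.0

    def test_repeat_one_matches_shorter_run(self):
        fm = separable_fm(80, seed=3)
        r1 = pf.cross_validate(fm, k=5, repeats=1, T=5, seed=11)
        r10 = pf.cross_validate(fm, k=5, repeats=4, T=5, seed=11)
        for metric in ("accuracy", "sensitivity", "specificity", "auc"):
            assert r1.raw[metric][0] == r10.raw[metric][0]

    def test_too_few_rows_per_class(self):
        with pytest.raises(ConfigError):
            pf.cross_validate(separable_fm(10), k=10)

    def test_metrics_in_range_and_report_shape(self):
        res = pf.cross_validate(noise_fm(100), k=5, repeats=2, T=5, seed=1)
        d = res.to_dict()
        for m in d["overall"].values():
            assert 0.0 <= m["mean"] <= 100.0
        assert set(d["per_consonant"]) == set(pf.CONSONANTS)
        assert d["protocol"]["k"] == 5

    def test_auc_extremes(self):
        y = np.arange(20) % 2 == 0
        assert roc_auc_score(y, y.astype(float)) == 1.0
        assert roc_auc_score(y, np.full(20, 0.3)) == 0.5


class TestFeatureMatrix:
    def test_combine_concatenates_dimensions(self):
        a = separable_fm()
        b = pf.FeatureMatrix(a.X * 2, a.labels.copy(), a.consonants.copy(),
                             [f"g_{i}" for i in range(3)])
        both = pf.FeatureMatrix.combine(a, b)
        assert both.n_features == a.n_features + b.n_features == 6

    def test_combine_rejects_label_mismatch(self):
        a = separable_fm()
        b = separable_fm()
        b.labels = b.labels[::-1].copy()
        with pytest.raises(ShapeError):
            pf.FeatureMatrix.combine(a, b)

    def test_frame_roundtrip(self):
        fm = separable_fm()
        df = fm.to_frame()
        back = pf.FeatureMatrix.from_frame(df)
        assert np.allclose(back.X, fm.X)
        assert np.array_equal(back.labels, fm.labels)

    def test_from_frame_prefix_selection(self):
        fm = separable_fm()
        df = fm.to_frame()
        df.columns = ["source_id", "consonant", "label", "p_1", "p_2", "df_1"]
        assert pf.FeatureMatrix.from_frame(df, prefix="p_").n_features == 2
        assert pf.FeatureMatrix.from_frame(df, prefix="df_").n_features == 1


class TestFeatureSignificance:
    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((120, 4))
        fm = make_fm(X, np.arange(120) % 2 == 0,
                     consonants=np.full(120, "s"))
        rep = pf.feature_significance(fm, per_consonant=False)
        assert rep[0]["H"] == 0

    def test_large_shift_detected(self):
        rng = np.random.default_rng(6)
        y = np.arange(100) % 2 == 0
        X = rng.standard_normal((100, 4)) + 3.0 * y[:, None]
        fm = make_fm(X, y, consonants=np.full(100, "s"))
        rep = pf.feature_significance(fm, per_consonant=False)
        assert rep[0]["H"] == 1
        assert rep[0]["p"] < 0.01

    def test_p_values_valid_per_consonant(self):
        rng = np.random.default_rng(7)
        fm = make_fm(rng.standard_normal((120, 4)), np.arange(120) % 2 == 0)
        for row in pf.feature_significance(fm):
            assert 0.0 <= row["p"] <= 1.0
            assert row["H"] in (0, 1)

    def test_empty_stratum_skipped(self):
        rng = np.random.default_rng(8)
        y = np.arange(40) % 2 == 0
        cons = np.where(y, "s", "sh")  # each consonant has one class only
        fm = make_fm(rng.standard_normal((40, 3)), y, consonants=cons)
        assert pf.feature_significance(fm) == []
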