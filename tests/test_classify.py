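import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from nosomap.classify import (
    FOUR_CLASS,
    THREE_CLASS,
    MetricsSummary,
    auc_ovr,
    baseline_classifiers,
    ber,
    bootstrap_evaluate,
    lda_fit,
    lda_predict,
    select_best_model,
)


class TestClassTask:
    def test_four_class_labels(self):
        assert FOUR_CLASS.classes == ("mm", "lgg", "agg", "no")
        assert THREE_CLASS.classes == ("mm", "agg", "no")

    def test_superclass_mapping(self):
        assert FOUR_CLASS.map_label("gb") == "agg"
        assert FOUR_CLASS.map_label("me") == "agg"
        assert FOUR_CLASS.map_label("mm") == "mm"
        assert THREE_CLASS.map_label("lgg") is None  # excluded from task


class TestLda:
    def test_1d_boundary_at_midpoint(self):
        X = np.concatenate([np.full(50, 0.0), np.full(50, 2.0)])[:, None]
        X = X + np.concatenate(
            [np.linspace(-1, 1, 50), np.linspace(-1, 1, 50)]
        )[:, None] * 1e-9  # break exact singularity
        y = np.array(["a"] * 50 + ["b"] * 50)
        model = lda_fit(X, y, ridge=1e-3)
        post, _ = lda_predict(model, np.array([[1.0]]))
        assert post[0, 0] == pytest.approx(0.5, abs=1e-6)

    def test_separated_clouds_zero_train_ber(self):
        rng = np.random.default_rng(0)
        X = np.concatenate(
            [rng.normal(0, 1, (100, 2)), rng.normal(10, 1, (100, 2))]
        )
        y = np.array(["a"] * 100 + ["b"] * 100)
        model = lda_fit(X, y)
        _, pred = lda_predict(model, X)
        assert ber(y, pred, ["a", "b"]) == 0.0

    def test_bayes_error_calibration(self):
        # two unit-variance Gaussians at -1/+1: Bayes error = Phi(-1)
        rng = np.random.default_rng(11)
        Xtr = np.concatenate(
            [rng.normal(-1, 1, (1000, 1)), rng.normal(1, 1, (1000, 1))]
        )
        ytr = np.array(["neg"] * 1000 + ["pos"] * 1000)
        Xte = np.concatenate(
            [rng.normal(-1, 1, (1000, 1)), rng.normal(1, 1, (1000, 1))]
        )
        model = lda_fit(Xtr, ytr)
        _, pred = lda_predict(model, Xte)
        from scipy.stats import norm

        bayes = norm.cdf(-1.0)
        assert abs(ber(ytr, pred, ["neg", "pos"]) - bayes) <= 0.03

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((60, 3))
        y = np.array(["a", "b", "c"] * 20)
        model = lda_fit(X, y)
        post, _ = lda_predict(model, rng.standard_normal((10, 3)))
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_far_class_mean_high_posterior(self):
        rng = np.random.default_rng(2)
        X = np.concatenate(
            [rng.normal(0, 1, (50, 2)), rng.normal(20, 1, (50, 2))]
        )
        y = np.array(["a"] * 50 + ["b"] * 50)
        model = lda_fit(X, y)
        post, _ = lda_predict(model, np.array([[20.0, 20.0]]))
        assert post[0, 1] > 0.99

    def test_priors_and_errors(self):
        X = np.ones((4, 2))
        y = np.array(["a", "a", "b", "b"])
        with pytest.raises(ValueError):
            lda_fit(X, y, ridge=0.0)  # singular without ridge
        model = lda_fit(X + np.arange(8).reshape(4, 2) * 0.1, y,
                        priors="uniform")
        assert np.allclose(model.priors, [0.5, 0.5])
        with pytest.raises(ValueError):
            lda_predict(model, np.ones((2, 3)))


class TestBer:
    def test_perfect(self):
        assert ber(["a", "b"], ["a", "b"], ["a", "b"]) == 0.0

    def test_printed_example(self):
        # class A 8/10 correct, class B 5/10 correct -> 0.35
        y_true = ["A"] * 10 + ["B"] * 10
        y_pred = ["A"] * 8 + ["B"] * 2 + ["B"] * 5 + ["A"] * 5
        assert ber(y_true, y_pred, ["A", "B"]) == pytest.approx(0.35)

    def test_everything_wrong(self):
        assert ber(["a", "b"], ["b", "a"], ["a", "b"]) == 1.0

    def test_absent_class_errors(self):
        with pytest.raises(ValueError):
            ber(["a", "a"], ["a", "a"], ["a", "b"])


class TestAuc:
    def test_perfect_separation(self):
        y = ["p", "p", "n", "n"]
        assert auc_ovr(y, np.array([0.9, 0.8, 0.2, 0.1]), "p") == 1.0

    def test_all_ties_half(self):
        y = ["p", "p", "n", "n"]
        assert auc_ovr(y, np.ones(4), "p") == 0.5

    def test_printed_example_three_quarters(self):
        # positives (0.9, 0.8), negatives (0.85, 0.7): 3 of 4 pairs correct
        y = ["p", "p", "n", "n"]
        scores = np.array([0.9, 0.8, 0.85, 0.7])
        assert auc_ovr(y, scores, "p") == pytest.approx(0.75)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(3)
        y = rng.choice(["p", "n"], 200)
        scores = rng.random(200)
        ours = auc_ovr(y, scores, "p")
        ref = roc_auc_score((y == "p").astype(int), scores)
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_inverted_scores_complement(self):
        rng = np.random.default_rng(4)
        y = rng.choice(["p", "n"], 100)
        scores = rng.standard_normal(100)
        assert auc_ovr(y, scores, "p") == pytest.approx(
            1.0 - auc_ovr(y, -scores, "p")
        )

    def test_degenerate_errors(self):
        with pytest.raises(ValueError):
            auc_ovr(["p", "p"], np.array([0.1, 0.2]), "p")


@pytest.fixture(scope="module")
def gaussian_problem():
    rng = np.random.default_rng(5)
    Xtr = np.concatenate(
        [rng.normal(0, 1, (40, 2)), rng.normal(3, 1, (40, 2))]
    )
    ytr = np.array(["a"] * 40 + ["b"] * 40)
    Xte = np.concatenate(
        [rng.normal(0, 1, (30, 2)), rng.normal(3, 1, (30, 2))]
    )
    yte = np.array(["a"] * 30 + ["b"] * 30)
    return Xtr, ytr, Xte, yte


class TestBootstrap:
    def test_no_resample_single_rep_degenerate(self, gaussian_problem):
        Xtr, ytr, Xte, yte = gaussian_problem
        ms = bootstrap_evaluate(
            Xtr, ytr, Xte, yte, n_reps=1, seed=0, resample=False
        )
        for arr in (ms.ber_train, ms.ber_test):
            agg = {"mean": arr.mean(), "min": arr.min(), "max": arr.max()}
            assert agg["mean"] == agg["min"] == agg["max"]

    def test_deterministic(self, gaussian_problem):
        Xtr, ytr, Xte, yte = gaussian_problem
        a = bootstrap_evaluate(Xtr, ytr, Xte, yte, n_reps=20, seed=3)
        b = bootstrap_evaluate(Xtr, ytr, Xte, yte, n_reps=20, seed=3)
        assert np.array_equal(a.ber_test, b.ber_test)
        assert np.array_equal(a.auc_test, b.auc_test)

    def test_default_reps_is_1000(self):
        import inspect

        sig = inspect.signature(bootstrap_evaluate)
        assert sig.parameters["n_reps"].default == 1000

    def test_metrics_bounded(self, gaussian_problem):
        Xtr, ytr, Xte, yte = gaussian_problem
        ms = bootstrap_evaluate(Xtr, ytr, Xte, yte, n_reps=10, seed=1)
        for arr in (ms.ber_train, ms.ber_test, ms.auc_train, ms.auc_test):
            assert np.all((arr >= 0) & (arr <= 1))

    def test_stratified_resample_keeps_classes(self, gaussian_problem):
        Xtr, ytr, Xte, yte = gaussian_problem
        # would raise inside ber() if a class vanished in any replicate
        bootstrap_evaluate(Xtr, ytr, Xte, yte, n_reps=50, seed=2)


class TestSelectBestModel:
    def _summary(self, auc_tr, auc_te, ber_te=0.2):
        reps = 3
        C = len(auc_tr)
        return MetricsSummary(
            classes=tuple("c%d" % i for i in range(C)),
            ber_train=np.full(reps, 0.1),
            ber_test=np.full(reps, ber_te),
            auc_train=np.tile(auc_tr, (reps, 1)).astype(float),
            auc_test=np.tile(auc_te, (reps, 1)).astype(float),
        )

    def test_single_candidate(self):
        ms = self._summary([0.9], [0.8])
        assert select_best_model([("only", ms)]) == "only"

    def test_ratio_closest_to_one_wins(self):
        a = self._summary([0.9], [0.9])  # ratio 1.0
        b = self._summary([0.95, 0.95], [0.95 * 0.8, 0.95 * 0.8])  # 0.8
        assert select_best_model([("A", a), ("B", b)]) == "A"

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            select_best_model([])

    def test_tie_break_by_order(self):
        a = self._summary([0.9], [0.9])
        b = self._summary([0.9], [0.9])
        assert select_best_model([("first", a), ("second", b)]) == "first"


class TestBaselines:
    def test_separable_zero_ber(self):
        rng = np.random.default_rng(6)
        X = np.concatenate(
            [rng.normal(0, 0.5, (40, 2)), rng.normal(10, 0.5, (40, 2))]
        )
        y = np.array(["a"] * 40 + ["b"] * 40)
        for method in ("rf", "svm"):
            model = baseline_classifiers(X, y, method, seed=0)
            _, pred = model.predict_posteriors(X)
            assert ber(y, pred, ["a", "b"]) == 0.0

    def test_rf_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((60, 4))
        y = np.array(["a", "b"] * 30)
        m1 = baseline_classifiers(X, y, "rf", seed=9)
        m2 = baseline_classifiers(X, y, "rf", seed=9)
        p1, _ = m1.predict_posteriors(X)
        p2, _ = m2.predict_posteriors(X)
        assert np.array_equal(p1, p2)

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            baseline_classifiers(np.ones((4, 2)), ["a", "a", "b", "b"], "mlp")
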