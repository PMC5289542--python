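import numpy as np
import pytest
from scipy import stats

from eigenvault.discriminant import (
    fit_classifier,
    loo_crossvalidate,
    mahalanobis_pairwise,
    stepwise_select,
    wilks_lambda,
)


def two_clouds(rng, n=15, gap=10.0, p=3):
    """Two well-separated Gaussian groups."""
    a = rng.normal(size=(n, p))
    b = rng.normal(size=(n, p))
    b[:, 0] += gap
    X = np.vstack([a, b])
    groups = np.array(["a"] * n + ["b"] * n)
    return X, groups


class TestWilksLambda:
    def test_equal_group_means_lambda_one(self):
        X = np.array([[0.0], [1.0], [0.0], [1.0]])
        groups = np.array(["a", "a", "b", "b"])
        lam, F, p = wilks_lambda(X, groups)
        assert lam == pytest.approx(1.0, abs=1e-12)
        assert F == pytest.approx(0.0, abs=1e-12)

    def test_hand_oracle_1d(self):
        # groups {0,1} vs {2,3}: W = 0.5+0.5 = 1, T = 5, lambda = 0.2;
        # Rao's F for p=1, g=2: F = (1-lam)/lam * (n-2)/1 = 8 on (1, 2) df
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        groups = np.array(["a", "a", "b", "b"])
        lam, F, p = wilks_lambda(X, groups)
        assert lam == pytest.approx(0.2, abs=1e-12)
        assert F == pytest.approx(8.0, abs=1e-10)
        assert p == pytest.approx(float(stats.f.sf(8.0, 1, 2)), abs=1e-12)

    def test_superset_never_increases_lambda(self, rng):
        X, groups = two_clouds(rng, p=4)
        lam_sub, _, _ = wilks_lambda(X, groups, [0, 1])
        lam_sup, _, _ = wilks_lambda(X, groups, [0, 1, 2])
        assert lam_sup <= lam_sub + 1e-12

    def test_empty_subset_error(self, rng):
        X, groups = two_clouds(rng)
        with pytest.raises(ValueError):
            wilks_lambda(X, groups, [])


class TestStepwise:
    def test_no_separation_gives_empty_selection(self, rng):
        half = rng.normal(size=(10, 3))
        X = np.vstack([half, half])  # group means exactly equal
        groups = np.array(["a"] * 10 + ["b"] * 10)
        assert stepwise_select(X, groups) == []

    def test_single_informative_variable_selected(self, rng):
        n = 15
        X = rng.normal(size=(2 * n, 4))
        X[n:, 1] += 8.0  # only variable 1 separates the groups
        groups = np.array(["a"] * n + ["b"] * n)
        assert stepwise_select(X, groups) == [1]

    def test_selection_respects_max_vars(self, rng):
        n = 30
        X = rng.normal(size=(2 * n, 12))
        X[n:] += 2.0  # every variable informative
        groups = np.array(["a"] * n + ["b"] * n)
        assert len(stepwise_select(X, groups, max_vars=6)) <= 6


class TestClassifier:
    def test_far_separated_clouds_fully_resubstituted(self, rng):
        X, groups = two_clouds(rng, gap=25.0)
        model = fit_classifier(X, groups, [0, 1, 2])
        assert model.accuracies() == {"a": 100.0, "b": 100.0}
        assert np.array_equal(model.confusion.sum(axis=1), [15, 15])

    def test_boundary_matches_closed_form_lda(self, rng):
        # equal-covariance two-group rule: assign by the sign of
        # w.(x - m) with w = Sinv (mu1 - mu2), m the midpoint of the means
        X, groups = two_clouds(rng, gap=4.0, p=2)
        sel = [0, 1]
        model = fit_classifier(X, groups, sel)
        mu_a, mu_b = model.group_means
        Sinv = np.linalg.inv(model.pooled_covariance)
        w = Sinv @ (mu_a - mu_b)
        mid = 0.5 * (mu_a + mu_b)
        probe = rng.normal(size=(200, 2)) * 3 + mid
        oracle = np.where(probe @ w - mid @ w > 0, "a", "b")
        np.testing.assert_array_equal(model.classify(probe), oracle)

    def test_matches_sklearn_lda(self, rng):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        n = 20
        X = rng.normal(size=(3 * n, 4))
        X[n : 2 * n, 0] += 3
        X[2 * n :, 1] += 3
        groups = np.array(["a"] * n + ["b"] * n + ["c"] * n)
        model = fit_classifier(X, groups, [0, 1, 2, 3])
        ours = model.classify(X)
        ref = sklearn.LinearDiscriminantAnalysis(
            priors=[1 / 3, 1 / 3, 1 / 3], solver="lsqr"
        ).fit(X, groups)
        np.testing.assert_array_equal(ours, ref.predict(X))

    def test_invariant_to_rescaling_a_variable(self, rng):
        X, groups = two_clouds(rng, gap=3.0)
        before = fit_classifier(X, groups, [0, 1, 2]).classify(X)
        X2 = X.copy()
        X2[:, 1] = X2[:, 1] * 40.0 - 7.0
        after = fit_classifier(X2, groups, [0, 1, 2]).classify(X2)
        np.testing.assert_array_equal(before, after)

    def test_wilks_trace_non_increasing(self, rng):
        X, groups = two_clouds(rng, gap=5.0, p=4)
        model = fit_classifier(X, groups, [0, 2, 3])
        assert all(b <= a + 1e-12
                   for a, b in zip(model.wilks_trace, model.wilks_trace[1:]))

    def test_empty_selection_error(self, rng):
        X, groups = two_clouds(rng)
        with pytest.raises(ValueError):
            fit_classifier(X, groups, [])


class TestCrossValidation:
    def test_well_separated_groups_perfect_loo(self, rng):
        X, groups = two_clouds(rng, gap=30.0)
        table, acc = loo_crossvalidate(X, groups, [0, 1, 2])
        assert acc == {"a": 100.0, "b": 100.0}
        assert np.array_equal(table.sum(axis=1), [15, 15])

    def test_loo_not_better_than_resubstitution_on_fixture(self, rng):
        X, groups = two_clouds(rng, gap=2.0)
        sel = [0, 1, 2]
        model = fit_classifier(X, groups, sel)
        _, cv_acc = loo_crossvalidate(X, groups, sel)
        resub = model.accuracies()
        mean_cv = np.mean(list(cv_acc.values()))
        mean_rs = np.mean(list(resub.values()))
        assert mean_cv <= mean_rs + 1e-9

    def test_small_group_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        groups = np.array(["a", "a", "a", "b", "b"])
        with pytest.raises(ValueError, match=">= 3"):
            loo_crossvalidate(X, groups, [0])


class TestMahalanobis:
    def test_identical_means_zero_distance(self):
        X = np.array([[0.0], [1.0], [0.0], [1.0]])
        groups = np.array(["a", "a", "b", "b"])
        out = mahalanobis_pairwise(X, groups, [0])
        assert out[("a", "b")]["D2"] == pytest.approx(0.0, abs=1e-12)

    def test_formula_oracle_1d(self):
        # means 0 and 2, pooled within-group variance 1 -> D2 = 4
        X = np.array([[-1.0], [0.0], [1.0], [1.0], [2.0], [3.0]])
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        out = mahalanobis_pairwise(X, groups, [0])
        res = out[("a", "b")]
        assert res["D2"] == pytest.approx(4.0, abs=1e-12)
        # Hotelling-style F: D2 * (n-g-k+1) * n1 n2 / (k (n-g)(n1+n2)) = 4.5
        assert res["F"] == pytest.approx(4.0 * 4 * 9 / (1 * 4 * 6), abs=1e-12)
        assert res["p"] == pytest.approx(float(stats.f.sf(res["F"], 1, 4)), abs=1e-12)

    def test_nonnegative_and_symmetric_by_construction(self, rng):
        n = 10
        X = rng.normal(size=(3 * n, 3))
        X[n : 2 * n] += 1.5
        groups = np.array(["a"] * n + ["b"] * n + ["c"] * n)
        out = mahalanobis_pairwise(X, groups, [0, 1, 2])
        assert len(out) == 3
        for v in out.values():
            assert v["D2"] >= 0
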