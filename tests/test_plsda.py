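"""NIPALS PLS-DA: component extraction, Q², VIP, and the validity gate.

The independent oracle throughout is scikit-learn's PLSRegression (NIPALS
with autoscaling) together with the textbook VIP formula evaluated directly
on the oracle's weights/scores/loadings.
"""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from hormsense.errors import DegenerateModelError, DesignError, FoldSchemeError
from hormsense.plsda import (
    compute_q2,
    compute_vip,
    fit_plsda,
    kfold_folds,
    loo_folds,
    validate_model,
)


def random_problem(rng, n=None, p=None, shift=0.0):
    n = n or int(rng.integers(6, 13))
    p = p or int(rng.integers(2, 9))
    n0 = n // 2
    X = rng.normal(size=(n, p))
    X[n0:, : max(1, p // 2)] += shift
    y = np.r_[np.zeros(n0), np.ones(n - n0)]
    return X, y


def sklearn_reference(X, y, A):
    """Oracle: sklearn fit plus the definitional VIP formula on its matrices."""
    sk = PLSRegression(n_components=A, scale=True).fit(X, y.reshape(-1, 1))
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    ssx = (Xs**2).sum()
    T, P, W, q = sk.x_scores_, sk.x_loadings_, sk.x_weights_, sk.y_loadings_.ravel()
    r2x_cum = np.cumsum(
        [(T[:, a] @ T[:, a]) * (P[:, a] @ P[:, a]) / ssx for a in range(A)]
    )
    ssy = np.array([(q[a] ** 2) * (T[:, a] @ T[:, a]) for a in range(A)])
    wnorm2 = W**2 / (W**2).sum(axis=0)
    vip = np.sqrt(X.shape[1] * (wnorm2 @ ssy) / ssy.sum())
    return sk, r2x_cum, vip


class TestFit:
    def test_separated_clouds_explain_response(self):
        rng = np.random.default_rng(0)
        X, y = random_problem(rng, n=6, p=5, shift=6.0)
        model = fit_plsda(X, y, 2)
        assert model.r2y > 0.9

    def test_single_variable_identity(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        model = fit_plsda(X, y, 1)
        assert model.weights[0, 0] == pytest.approx(1.0)
        Xs = (X[:, 0] - X[:, 0].mean()) / X[:, 0].std(ddof=1)
        np.testing.assert_allclose(model.scores[:, 0], Xs, atol=1e-12)
        np.testing.assert_allclose(compute_vip(model), [1.0], atol=1e-12)

    def test_first_weight_is_normalized_cross_covariance(self):
        # for a single response the first NIPALS weight is X_s'y_c normalized,
        # i.e. the dominant left singular vector of the p x 1 cross-covariance
        rng = np.random.default_rng(3)
        X, y = random_problem(rng, n=10, p=6)
        model = fit_plsda(X, y, 1)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        w_expected = Xs.T @ (y - y.mean())
        w_expected /= np.linalg.norm(w_expected)
        sign = np.sign(w_expected[np.flatnonzero(np.abs(w_expected) > 1e-12)[0]])
        np.testing.assert_allclose(model.weights[:, 0], sign * w_expected, atol=1e-10)

    def test_one_class_absent_raises(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        with pytest.raises(DesignError):
            fit_plsda(X, np.zeros(6), 2)

    def test_component_count_truncated_to_rank(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(6, 1))
        X = np.hstack([base, 2 * base, -base])  # rank 1
        y = np.r_[np.zeros(3), np.ones(3)]
        with pytest.warns(UserWarning, match="rank"):
            model = fit_plsda(X, y, 3)
        assert model.n_components == 1

    def test_zero_variance_column_dropped_with_zero_vip(self):
        rng = np.random.default_rng(2)
        X, y = random_problem(rng, n=8, p=4, shift=3.0)
        X[:, 2] = 5.0
        with pytest.warns(UserWarning, match="zero-variance"):
            model = fit_plsda(X, y, 2)
        vip = compute_vip(model)
        assert vip[2] == 0.0
        assert len(vip) == 4

    def test_invariants_on_random_suite(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            X, y = random_problem(rng)
            A = int(rng.integers(1, 4))
            model = fit_plsda(X, y, A)
            # unit-norm weights
            np.testing.assert_allclose(
                np.linalg.norm(model.weights, axis=0), 1.0, atol=1e-10
            )
            # orthogonal scores
            T = model.scores
            for i in range(model.n_components):
                for j in range(i + 1, model.n_components):
                    assert abs(T[:, i] @ T[:, j]) < 1e-6 * np.linalg.norm(
                        T[:, i]
                    ) * np.linalg.norm(T[:, j])
            # cumulative variance fractions are monotone and bounded
            assert np.all(np.diff(model.r2x_cumulative) >= -1e-12)
            assert np.all(np.diff(model.r2y_cumulative) >= -1e-12)
            assert 0 <= model.r2x <= 1 + 1e-12
            assert 0 <= model.r2y <= 1 + 1e-12


class TestOracleEquivalence:
    def test_matches_sklearn_on_random_problems(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            X, y = random_problem(rng)
            A = 2
            model = fit_plsda(X, y, A)
            if model.n_components < A:
                continue
            sk, r2x_cum, vip_ref = sklearn_reference(X, y, A)
            np.testing.assert_allclose(model.r2x_cumulative, r2x_cum, atol=1e-6)
            np.testing.assert_allclose(compute_vip(model), vip_ref, atol=1e-6)
            np.testing.assert_allclose(
                np.abs(model.scores), np.abs(sk.x_scores_), atol=1e-6
            )
            np.testing.assert_allclose(
                np.abs(model.x_loadings), np.abs(sk.x_loadings_), atol=1e-6
            )

    def test_predictions_match_sklearn(self):
        rng = np.random.default_rng(8)
        X, y = random_problem(rng, n=10, p=5, shift=2.0)
        model = fit_plsda(X, y, 2)
        sk = PLSRegression(n_components=2, scale=True).fit(X, y.reshape(-1, 1))
        np.testing.assert_allclose(
            model.predict(X), sk.predict(X).ravel(), atol=1e-8
        )


class TestQ2:
    @staticmethod
    def separable_problem(seed, n=6, p=5, shift=6.0):
        """Two classes separated by `shift` pooled SDs along every variable:
        one planted direction, so one component captures the signal."""
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        X[n // 2 :, :] += shift
        return X, np.r_[np.zeros(n // 2), np.ones(n - n // 2)]

    def test_separable_data_has_high_q2(self):
        X, y = self.separable_problem(0)
        assert compute_q2(X, y, 1) > 0.9

    def test_permuted_labels_have_nonpositive_mean_q2(self):
        X, y = self.separable_problem(1)
        rng = np.random.default_rng(1)
        q2s = []
        for _ in range(100):
            perm = rng.permutation(y)
            q2s.append(compute_q2(X, perm, 1))
        assert np.mean(q2s) <= 0

    def test_oracle_cv_loop(self):
        """Independent LOO loop around the sklearn fit gives the same Q²."""
        rng = np.random.default_rng(5)
        X, y = random_problem(rng, n=8, p=4, shift=2.0)
        press = tss = 0.0
        for i in range(len(y)):
            tr = np.setdiff1d(np.arange(len(y)), [i])
            sk = PLSRegression(n_components=2, scale=True).fit(
                X[tr], y[tr].reshape(-1, 1)
            )
            pred = sk.predict(X[[i]]).ravel()[0]
            press += (y[i] - pred) ** 2
            tss += (y[i] - y[tr].mean()) ** 2
        assert compute_q2(X, y, 2) == pytest.approx(1 - press / tss, abs=1e-8)

    def test_fold_emptying_a_class_raises(self):
        X = np.random.default_rng(0).normal(size=(4, 3))
        y = np.array([0.0, 0.0, 0.0, 1.0])
        with pytest.raises(FoldSchemeError):
            compute_q2(X, y, 1, folds=[np.array([3]), np.array([0, 1, 2])])

    def test_kfold_scheme_runs(self):
        rng = np.random.default_rng(9)
        X, y = random_problem(rng, n=12, p=5, shift=4.0)
        q2 = compute_q2(X, y, 2, folds=kfold_folds(12, 3, seed=0))
        assert q2 > 0.5


class TestVip:
    def test_sum_of_squares_equals_p(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            X, y = random_problem(rng)
            model = fit_plsda(X, y, 2)
            vip = compute_vip(model)
            assert (vip**2).sum() == pytest.approx(X.shape[1], abs=1e-8)

    def test_degenerate_model_raises(self):
        rng = np.random.default_rng(12)
        X, y = random_problem(rng, n=8, p=4)
        model = fit_plsda(X, y, 1)
        model.ssy_per_component = np.zeros(1)
        with pytest.raises(DegenerateModelError):
            compute_vip(model)


class TestValidityGate:
    @pytest.mark.parametrize(
        "metrics, passed, failing",
        [
            ((0.636, 0.999, 0.838), True, set()),
            ((0.741, 0.984, 0.909), True, set()),
            ((0.4, 0.99, 0.9), False, {"r2x"}),
            ((0.5, 0.5, 0.5), False, {"r2x", "r2y", "q2"}),
            ((0.9, 0.9, 0.2), False, {"q2"}),
        ],
    )
    def test_strict_threshold(self, metrics, passed, failing):
        verdict = validate_model(*metrics)
        assert verdict.passed is passed
        assert {k for k, ok in verdict.flags.items() if not ok} == failing


def test_loo_folds_cover_all_samples():
    folds = loo_folds(6)
    assert sorted(int(f[0]) for f in folds) == list(range(6))
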