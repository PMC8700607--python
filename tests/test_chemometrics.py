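"""Numerical-engine tests: PCA and NIPALS PLS against independent
oracles, venetian-blind cross-validation, and latent-variable selection."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from teafp import chemometrics
from teafp.chemometrics import (
    NipalsPls,
    Pca,
    cross_validate_pls,
    model_from_json,
    model_to_json,
    pls_fit,
    select_lv,
    venetian_blind_splits,
)
from teafp.preprocess import autoscale


class TestPca:
    def test_collinear_points_single_component(self):
        X = np.array([[1.0, 2.0], [2.0, 4.0], [-1.0, -2.0], [0.5, 1.0]])
        model = Pca().fit(X)
        assert model.explained_variance_ratio_[0] == pytest.approx(1.0)

    def test_full_reconstruction(self, rng):
        X = rng.normal(size=(6, 4))
        model = Pca().fit(X)
        np.testing.assert_allclose(
            model.scores_ @ model.loadings_.T, X, atol=1e-8
        )

    def test_matches_svd_oracle_up_to_sign(self, rng):
        X, _, _ = autoscale(rng.normal(size=(6, 4)))
        model = Pca().fit(X)
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        np.testing.assert_allclose(np.abs(model.loadings_), np.abs(Vt.T), atol=1e-9)
        np.testing.assert_allclose(np.abs(model.scores_), np.abs(U * s), atol=1e-9)
        np.testing.assert_allclose(
            model.explained_variance_ratio_, s**2 / np.sum(s**2), atol=1e-12
        )

    def test_loadings_orthonormal_and_variance_ordered(self, rng):
        X = rng.normal(size=(8, 5))
        model = Pca().fit(X)
        np.testing.assert_allclose(
            model.loadings_.T @ model.loadings_, np.eye(5), atol=1e-9
        )
        ev = model.explained_variance_ratio_
        assert np.all(np.diff(ev) <= 1e-12) and ev.sum() <= 1 + 1e-9

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            Pca(5).fit(rng.normal(size=(4, 3)))


class TestNipalsPls:
    def test_single_informative_column_perfect_fit(self, rng):
        """y proportional to one X column: one LV suffices (exactly so
        for orthogonal columns, where w = e_j and t spans y)."""
        X, _ = np.linalg.qr(rng.normal(size=(10, 5)))
        y = 3.0 * X[:, 2]
        model = NipalsPls(n_components=1, scale=False).fit(X, y)
        fitted = model.predict(X)
        ss_res = np.sum((y - fitted) ** 2)
        assert 1.0 - ss_res / np.sum((y - y.mean()) ** 2) > 1 - 1e-8

    def test_full_rank_equals_least_squares(self, rng):
        """With as many LVs as the rank, PLS reproduces the OLS fit."""
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        model = pls_fit(X, y, n_lv=4)
        fitted = model.predict(X)
        A = np.column_stack([np.ones(10), X])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        np.testing.assert_allclose(fitted, A @ beta, atol=1e-6)

    def test_sample_order_invariance(self, rng):
        X = rng.normal(size=(12, 6))
        y = rng.normal(size=12)
        perm = rng.permutation(12)
        a = pls_fit(X, y, 3)
        b = pls_fit(X[perm], y[perm], 3)
        np.testing.assert_allclose(a.coef_, b.coef_, atol=1e-9)

    def test_scores_mutually_orthogonal(self, rng):
        X = rng.normal(size=(15, 8))
        Y = rng.normal(size=(15, 2))
        T = pls_fit(X, Y, 4).x_scores_
        G = T.T @ T
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-8)

    def test_matches_hand_rolled_first_component(self, rng):
        """First LV of a tiny problem against a literal NIPALS transcription."""
        X = rng.normal(size=(10, 5))
        y = rng.normal(size=10)
        model = pls_fit(X, y, 1)
        Xc, _, _ = autoscale(X)
        yc = y - y.mean()
        w = Xc.T @ yc
        w /= np.linalg.norm(w)
        if w[np.argmax(np.abs(w))] < 0:
            w = -w
        t = Xc @ w
        np.testing.assert_allclose(model.x_weights_[:, 0], w, atol=1e-10)
        np.testing.assert_allclose(model.x_scores_[:, 0], t, atol=1e-10)

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(12, 7))
        y = X @ rng.normal(size=7) + 0.1 * rng.normal(size=12)
        ours = pls_fit(X, y, 3).predict(X)
        theirs = np.ravel(PLSRegression(n_components=3, scale=True).fit(X, y).predict(X))
        np.testing.assert_allclose(ours, theirs, atol=1e-8)

    def test_zero_variance_y_rejected(self, rng):
        with pytest.raises(ValueError, match="variance"):
            pls_fit(rng.normal(size=(6, 3)), np.full(6, 2.0), 1)

    def test_coefficients_reproduce_fitted_values(self, rng):
        X = rng.normal(size=(9, 6))
        y = rng.normal(size=9)
        model = pls_fit(X, y, 2)
        Xs = (X - model.x_mean_) / model.x_std_
        np.testing.assert_allclose(
            Xs @ model.coef_[:, 0] + model.y_mean_[0], model.predict(X), atol=1e-10
        )


class TestPlsPredict:
    def test_training_rows_reproduce_fit(self, rng):
        X = rng.normal(size=(8, 5))
        y = rng.normal(size=8)
        model = pls_fit(X, y, 2)
        np.testing.assert_allclose(model.predict(X), model.predict(X.copy()))

    def test_centered_row_predicts_training_mean(self, rng):
        X = rng.normal(size=(8, 5))
        y = rng.normal(size=8)
        model = pls_fit(X, y, 2)
        assert model.predict(X.mean(axis=0))[0] == pytest.approx(y.mean())

    def test_manual_dot_product(self, rng):
        X = rng.normal(size=(8, 5))
        y = rng.normal(size=8)
        model = pls_fit(X, y, 2)
        x_new = rng.normal(size=5)
        by_hand = ((x_new - model.x_mean_) / model.x_std_) @ model.coef_[:, 0]
        assert model.predict(x_new)[0] == pytest.approx(
            by_hand + model.y_mean_[0], abs=1e-10
        )

    def test_column_mismatch_rejected(self, rng):
        model = pls_fit(rng.normal(size=(8, 5)), rng.normal(size=8), 2)
        with pytest.raises(ValueError, match="column"):
            model.predict(np.zeros((2, 4)))

    def test_json_round_trip(self, rng):
        X = rng.normal(size=(8, 5))
        y = rng.normal(size=8)
        model = pls_fit(X, y, 2)
        clone = model_from_json(model_to_json(model))
        np.testing.assert_allclose(clone.predict(X), model.predict(X), atol=1e-12)


class TestVenetianBlinds:
    def test_interleaving_definition(self):
        splits = venetian_blind_splits(6, 3)
        assert [list(test) for _, test in splits] == [[0, 3], [1, 4], [2, 5]]

    def test_loo_when_splits_equal_samples(self):
        splits = venetian_blind_splits(5, 5)
        assert [list(test) for _, test in splits] == [[0], [1], [2], [3], [4]]

    @given(n=st.integers(4, 40), k=st.integers(2, 10))
    def test_partition_property(self, n, k):
        k = min(k, n)
        splits = venetian_blind_splits(n, k)
        tests = np.concatenate([test for _, test in splits])
        assert sorted(tests.tolist()) == list(range(n))
        for train, test in splits:
            assert np.intersect1d(train, test).size == 0

    def test_invalid_split_counts_rejected(self):
        with pytest.raises(ValueError):
            venetian_blind_splits(3, 4)
        with pytest.raises(ValueError):
            venetian_blind_splits(5, 1)


class TestCrossValidation:
    def test_noiseless_single_factor_near_zero_error(self, rng):
        t = rng.normal(size=20)
        X = np.outer(t, rng.normal(size=6))
        y = 2.0 * t
        cv = cross_validate_pls(X, y, max_lv=2, n_splits=5)
        assert cv.rmsecv_by_lv[0] < 1e-6

    def test_shuffled_response_stays_at_null_level(self, rng):
        X = rng.normal(size=(30, 10))
        y = rng.permutation(np.repeat(np.arange(5.0), 6))
        cv = cross_validate_pls(X, y, max_lv=4, n_splits=10)
        assert np.all(cv.rmsecv_by_lv >= 0.8 * np.std(y))

    def test_fit_count_bookkeeping(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        cv = cross_validate_pls(X, y, max_lv=2, n_splits=5)
        assert cv.n_fits == 5 * 2

    def test_scaling_never_sees_test_rows(self, rng):
        """A wild-valued test row must not perturb training coefficients."""
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        splits = venetian_blind_splits(10, 5)
        train, test = splits[0]
        model_a = pls_fit(X[train], y[train], 2)
        X2 = X.copy()
        X2[test[0]] = 1e6
        model_b = pls_fit(X2[train], y[train], 2)
        np.testing.assert_array_equal(model_a.coef_, model_b.coef_)


class TestSelectLv:
    @pytest.mark.parametrize(
        "curve, expected",
        [
            ([5.0, 3.0, 2.9, 3.2], 3),
            ([4.0, 3.0, 2.0, 1.0], 4),  # strictly decreasing -> last
            ([2.0, 2.0, 2.0], 1),  # earliest of equals
            ([1.0], 1),
        ],
    )
    def test_first_important_minimum_rule(self, curve, expected):
        assert select_lv(curve, rel_tol=0.02) == expected

    @given(
        st.lists(st.floats(0.1, 100.0), min_size=1, max_size=10),
        st.floats(0.0, 0.2),
    )
    def test_selection_matches_brute_force(self, curve, tol):
        r = np.asarray(curve)
        chosen = select_lv(r, rel_tol=tol)
        assert 1 <= chosen <= r.size
        # literal restatement of the rule over all candidates
        for L in range(r.size):
            later = r[L + 1 :]
            ok = later.size == 0 or r[L] <= (1 + tol) * later.min()
            if ok:
                assert chosen == L + 1
                break
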