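"""SIMPLS regression, VIP scores, leave-one-out CV, VIP-based reduction.

Oracles are kept independent of the implementation: ordinary least squares
via numpy, a NIPALS PLS1 coded here from the textbook recursion, a direct
loop-free evaluation of the VIP formula, and a manual refit loop for the
cross-validation.
"""

import numpy as np
import pandas as pd
import pytest

from evuptake.pls import (
    CVResult,
    evaluate_test,
    fit_simpls,
    loo_cv,
    predict,
    reduce_by_vip,
    train_pls,
    vip_scores,
)
from evuptake.pls import _autoscale


def nipals_pls1(X, y, n_components):
    """Textbook NIPALS PLS1 on centered data; returns coefficients."""
    Xa = X.copy()
    ya = y.copy().astype(float)
    W, P, q = [], [], []
    for _ in range(n_components):
        w = Xa.T @ ya
        w = w / np.linalg.norm(w)
        t = Xa @ w
        tt = t @ t
        p = Xa.T @ t / tt
        qa = (ya @ t) / tt
        Xa = Xa - np.outer(t, p)
        ya = ya - t * qa
        W.append(w)
        P.append(p)
        q.append(qa)
    W, P, q = np.array(W).T, np.array(P).T, np.array(q)
    return W @ np.linalg.solve(P.T @ W, q)


def _centered(rng, n, p, m):
    X = rng.normal(size=(n, p))
    Y = rng.normal(size=(n, m))
    return X - X.mean(axis=0), Y - Y.mean(axis=0)


class TestSIMPLS:
    def test_full_rank_equals_ols(self, rng):
        for _ in range(5):
            Xc, Yc = _centered(rng, 10, 6, 6)
            R, P, Q, T, xv, yv = fit_simpls(Xc, Yc, 6)
            B_ols = np.linalg.lstsq(Xc, Yc, rcond=None)[0]
            np.testing.assert_allclose(R @ Q.T, B_ols, atol=1e-6)

    @pytest.mark.parametrize("n_components", [1, 2, 3])
    def test_single_outcome_matches_nipals_pls1(self, rng, n_components):
        Xc, yc = _centered(rng, 12, 8, 1)
        yc = yc.ravel()
        R, P, Q, T, _, _ = fit_simpls(Xc, yc, n_components)
        b_nipals = nipals_pls1(Xc, yc, n_components)
        np.testing.assert_allclose(
            Xc @ (R @ Q.T).ravel(), Xc @ b_nipals, atol=1e-8
        )

    def test_noiseless_linear_response_fully_explained(self, rng):
        Xc, _ = _centered(rng, 10, 4, 1)
        b = rng.normal(size=(4, 2))
        Yc = Xc @ b
        R, P, Q, T, xv, yv = fit_simpls(Xc, Yc, 4)
        np.testing.assert_allclose(Xc @ (R @ Q.T), Yc, atol=1e-10)
        assert yv.sum() == pytest.approx(1.0, abs=1e-10)

    def test_score_orthogonality(self, rng):
        for _ in range(5):
            Xc, Yc = _centered(rng, 15, 40, 3)
            _, _, _, T, _, _ = fit_simpls(Xc, Yc, 5)
            np.testing.assert_allclose(T.T @ T, np.eye(5), atol=1e-8)

    def test_cumulative_variance_non_decreasing_and_bounded(self, rng):
        Xc, Yc = _centered(rng, 12, 20, 4)
        _, _, _, _, xv, yv = fit_simpls(Xc, Yc, 6)
        assert (xv >= -1e-12).all() and (yv >= -1e-12).all()
        assert xv.sum() <= 1 + 1e-8
        assert yv.sum() <= 1 + 1e-8

    def test_too_many_components_rejected(self, rng):
        Xc, Yc = _centered(rng, 6, 10, 2)
        with pytest.raises(ValueError, match="n_components"):
            fit_simpls(Xc, Yc, 6)

    def test_degenerate_cross_product_rejected(self):
        X = np.diag([1.0, 2.0, 3.0]) - 2.0
        with pytest.raises(ValueError, match="degenerate"):
            fit_simpls(X - X.mean(0), np.zeros((3, 2)), 1)

    def test_deterministic_fit(self, rng):
        Xc, Yc = _centered(rng, 10, 30, 6)
        out1 = fit_simpls(Xc, Yc, 3)
        out2 = fit_simpls(Xc.copy(), Yc.copy(), 3)
        for a, b in zip(out1, out2):
            np.testing.assert_array_equal(a, b)


class TestPredict:
    def test_training_predictions_consistent(self, rng):
        X = pd.DataFrame(rng.normal(5, 1, size=(10, 7)),
                         columns=[f"F{i}" for i in range(7)])
        Y = pd.DataFrame(rng.normal(1, 0.3, size=(10, 2)),
                         columns=["a", "b"])
        model = train_pls(X, Y, 3)
        Xs = (X.to_numpy() - model.x_center) / model.x_scale
        manual = Xs @ model.coefficients() * model.y_scale + model.y_center
        np.testing.assert_allclose(predict(model, X).to_numpy(), manual)

    def test_mean_input_predicts_outcome_mean(self, rng):
        X = pd.DataFrame(rng.normal(size=(8, 5)),
                         columns=[f"F{i}" for i in range(5)])
        Y = pd.DataFrame(rng.normal(size=(8, 2)), columns=["a", "b"])
        model = train_pls(X, Y, 2)
        row = pd.DataFrame([X.mean(axis=0)], columns=X.columns)
        np.testing.assert_allclose(
            predict(model, row).to_numpy().ravel(), model.y_center, atol=1e-10
        )

    def test_truncation_adds_exactly_the_second_component(self, rng):
        # predictions at A=2 differ from A=1 by t₂q₂ᵀ (rescaled), hence are
        # identical exactly when the component-2 Y loadings are zero
        X = pd.DataFrame(rng.normal(size=(10, 6)),
                         columns=[f"F{i}" for i in range(6)])
        Y = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        model = train_pls(X, Y, 2)
        p1 = predict(model, X, n_components=1).to_numpy()
        p2 = predict(model, X, n_components=2).to_numpy()
        assert np.abs(p1 - p2).max() > 1e-6
        second = np.outer(model.scores[:, 1],
                          model.y_loadings[:, 1]) * model.y_scale
        np.testing.assert_allclose(p2 - p1, second, atol=1e-10)

    def test_component_beyond_data_rank_is_rejected(self, rng):
        # exactly rank-one X: a second component has nothing left to fit
        t = rng.normal(size=10)
        X1 = pd.DataFrame(np.outer(t, rng.normal(size=6)) + 5,
                          columns=[f"F{i}" for i in range(6)])
        Y1 = pd.DataFrame(np.outer(t, rng.normal(size=2)) + 1,
                          columns=["a", "b"])
        assert train_pls(X1, Y1, 1).n_components == 1
        with pytest.raises(ValueError, match="degenerate"):
            train_pls(X1, Y1, 2)

    def test_feature_mismatch_reported(self, rng):
        X = pd.DataFrame(rng.normal(size=(8, 4)),
                         columns=["F0", "F1", "F2", "F3"])
        Y = pd.DataFrame(rng.normal(size=(8, 2)), columns=["a", "b"])
        model = train_pls(X, Y, 2)
        bad = X.rename(columns={"F3": "F9"})
        with pytest.raises(ValueError, match="F3"):
            predict(model, bad)


class TestVIP:
    def test_sum_of_squares_identity(self, rng):
        for p in (8, 40):
            X = pd.DataFrame(rng.normal(size=(10, p)))
            Y = pd.DataFrame(rng.normal(size=(10, 6)))
            model = train_pls(X, Y, 3)
            vip = vip_scores(model)
            np.testing.assert_allclose(
                (vip.per_outcome ** 2).sum(axis=0), p, atol=1e-8
            )

    def test_single_active_feature_collapses(self):
        # only feature 1 varies with y: its weight is the whole component
        n, p = 12, 5
        rng = np.random.default_rng(7)
        t = rng.normal(size=n)
        X = np.zeros((n, p))
        X[:, 0] = t
        y = 2.0 * t
        R, P, Q, T, _, _ = fit_simpls(
            X - X.mean(0), (y - y.mean())[:, None], 1
        )
        from evuptake.pls import PLSModel
        model = PLSModel(
            weights=R, x_loadings=P, y_loadings=Q, scores=T,
            x_variance_explained=np.zeros(1), y_variance_explained=np.zeros(1),
            x_center=np.zeros(p), x_scale=np.ones(p),
            y_center=np.zeros(1), y_scale=np.ones(1),
        )
        vip = vip_scores(model)
        np.testing.assert_allclose(vip.per_outcome.iloc[0, 0], np.sqrt(p))
        np.testing.assert_allclose(vip.per_outcome.iloc[1:, 0], 0, atol=1e-12)

    def test_matches_direct_formula(self, rng):
        X = pd.DataFrame(rng.normal(size=(8, 5)))
        Y = pd.DataFrame(rng.normal(size=(8, 2)))
        model = train_pls(X, Y, 3)
        vip = vip_scores(model)
        W, Q, T = model.weights, model.y_loadings, model.scores
        p, A = W.shape
        expected = np.zeros((p, Q.shape[0]))
        for k in range(Q.shape[0]):
            ss = np.array([Q[k, a] ** 2 * (T[:, a] @ T[:, a])
                           for a in range(A)])
            for j in range(p):
                num = sum(ss[a] * (W[j, a] / np.linalg.norm(W[:, a])) ** 2
                          for a in range(A))
                expected[j, k] = np.sqrt(p * num / ss.sum())
        np.testing.assert_allclose(vip.per_outcome.to_numpy(), expected,
                                   atol=1e-10)

    def test_selection_is_strict(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 6)))
        Y = pd.DataFrame(rng.normal(size=(10, 2)))
        vip = vip_scores(train_pls(X, Y, 2))
        threshold = float(vip.average.iloc[0])
        again = vip_scores(train_pls(X, Y, 2), threshold=threshold)
        assert vip.average.index[0] not in again.selected


class TestLOOCV:
    def test_matches_manual_refit_loop(self, rng):
        X = rng.normal(size=(6, 9))
        Y = rng.normal(size=(6, 3))
        cv = loo_cv(X, Y, 2)
        Xs, _, _ = _autoscale(X, True, True)
        Ys, yc, ys = _autoscale(Y, True, True)
        press = np.zeros(3)
        for i in range(6):
            mask = np.ones(6, dtype=bool)
            mask[i] = False
            R, P, Q, T, _, _ = fit_simpls(Xs[mask], Ys[mask], 2)
            pred = Xs[i] @ (R @ Q.T) * ys + yc
            press += (Y[i] - pred) ** 2
        np.testing.assert_array_equal(cv.press.to_numpy(), press)

    def test_metric_identities(self, rng):
        X = rng.normal(size=(8, 5))
        Y = rng.normal(size=(8, 2))
        cv = loo_cv(X, Y, 2)
        tss = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
        np.testing.assert_allclose(cv.r2.to_numpy(),
                                   1 - cv.press.to_numpy() / tss)
        np.testing.assert_allclose(cv.rmse.to_numpy(),
                                   np.sqrt(cv.press.to_numpy() / 8))

    def test_noiseless_linear_response_r2_one(self, rng):
        X = rng.normal(size=(30, 4))
        Y = X @ rng.normal(size=(4, 2)) + 3.0
        cv = loo_cv(X, Y, 4)
        assert (cv.r2 > 0.999).all()

    def test_permuted_response_r2_not_positive_on_average(self):
        r2s = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(12, 20))
            y = X @ rng.normal(size=(20, 1))
            y_perm = y[rng.permutation(12)]
            r2s.append(loo_cv(X, y_perm, 2).r2.mean())
        assert np.mean(r2s) <= 0

    def test_component_bound(self, rng):
        X = rng.normal(size=(6, 9))
        Y = rng.normal(size=(6, 2))
        with pytest.raises(ValueError, match="n_components"):
            loo_cv(X, Y, 5)


class TestReduceByVIP:
    def test_threshold_zero_keeps_all_features(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 8)),
                         columns=[f"F{i}" for i in range(8)])
        Y = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        red = reduce_by_vip(X, Y, threshold=0.0)
        assert list(red.vip.selected) == list(X.columns)
        assert red.reduced_model.n_features == 8

    def test_unreachable_threshold_errors(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 8)),
                         columns=[f"F{i}" for i in range(8)])
        Y = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        top = vip_scores(train_pls(X, Y, 3)).average.max()
        with pytest.raises(ValueError, match="VIP"):
            reduce_by_vip(X, Y, threshold=top + 1.0)

    def test_components_and_artifacts(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 30)),
                         columns=[f"F{i}" for i in range(30)])
        Y = pd.DataFrame(rng.normal(size=(12, 6)))
        red = reduce_by_vip(X, Y)
        assert red.full_model.n_components == 3
        assert red.reduced_model.n_components == 2
        assert isinstance(red.cv_full, CVResult)
        assert list(red.reduced_model.feature_names) == list(red.vip.selected)


class TestEvaluateTest:
    def test_training_set_reproduces_fit_metrics(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 6)),
                         columns=[f"F{i}" for i in range(6)])
        Y = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        model = train_pls(X, Y, 2)
        metrics = evaluate_test(model, X, Y)
        resid = Y - predict(model, X)
        rss = (resid ** 2).sum()
        tss = ((Y - Y.mean()) ** 2).sum()
        np.testing.assert_allclose(metrics.loc[["a", "b"], "r2"],
                                   1 - rss / tss)

    def test_constant_prediction_gives_r2_zero(self):
        # a model fed its own training mean predicts y_center everywhere,
        # which is the test mean here, so R2 is exactly zero by definition
        rng = np.random.default_rng(3)
        Y = pd.DataFrame(rng.normal(size=(6, 2)), columns=["a", "b"])
        X_fit = pd.DataFrame(rng.normal(size=(6, 3)),
                             columns=["F0", "F1", "F2"])
        model = train_pls(X_fit, Y, 2)
        X_mean = pd.DataFrame(
            np.tile(X_fit.mean(axis=0), (6, 1)), columns=X_fit.columns
        )
        metrics = evaluate_test(model, X_mean, Y + 0)
        # predictions are all y_center = test mean here, so R2 = 0
        np.testing.assert_allclose(metrics.loc[["a", "b"], "r2"], 0,
                                   atol=1e-8)
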