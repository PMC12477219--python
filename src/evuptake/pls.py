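"""Multi-response PLS regression (SIMPLS), VIP selection, cross-validation.

This module is the analytical core of the package and is implemented from
first principles.

SIMPLS (de Jong 1993) extracts components by deflating the X–Y cross-product
matrix S = XᵀY rather than X itself. Per component *a*:

    rₐ  = dominant left singular vector of S         (weight)
    tₐ  = X rₐ, normalized to unit length             (score)
    pₐ  = Xᵀ tₐ                                       (X loading)
    qₐ  = Yᵀ tₐ                                       (Y loading)
    vₐ  = pₐ orthogonalized against v₁..vₐ₋₁, normalized
    S  ← S − vₐ (vₐᵀ S)

Regression coefficients on the autoscaled space are B = R Qᵀ, truncatable
to any number of leading components. With unit-norm scores, per-component
explained variances are ‖pₐ‖²/‖X‖²_F and ‖qₐ‖²/‖Y‖²_F.

Variable importance in projection for outcome k, with SSₐₖ = qₐₖ²(tₐᵀtₐ):

    VIPⱼₖ = √( p · Σₐ SSₐₖ (rⱼₐ/‖rₐ‖)² / Σₐ SSₐₖ )

so that Σⱼ VIPⱼₖ² = p for every outcome. The multi-response score is the
mean over outcomes, and the standard selection rule keeps features with
mean VIP strictly greater than 1.

The model-reduction procedure mirrors common chemometrics practice for
small-n omics regressions: a 3-component model on all features with
leave-one-out cross-validation, VIP>1 feature selection averaged over all
six uptake outcomes, then a final 2-component model on the selected
features, evaluated on a held-out condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PLSModel", "VIPResult", "CVResult", "PLSReduction",
    "fit_simpls", "train_pls", "predict", "vip_scores", "loo_cv",
    "reduce_by_vip", "evaluate_test",
]


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """Fitted SIMPLS model with its preprocessing record.

    All matrices refer to the autoscaled space; ``x_center``/``x_scale`` and
    ``y_center``/``y_scale`` map between raw and autoscaled coordinates.
    """

    weights: np.ndarray            # p × A  (R: scores T = Xs · R)
    x_loadings: np.ndarray         # p × A
    y_loadings: np.ndarray         # m × A
    scores: np.ndarray             # n × A, unit columns
    x_variance_explained: np.ndarray   # (A,) fractions
    y_variance_explained: np.ndarray   # (A,) fractions
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: np.ndarray
    y_scale: np.ndarray
    feature_names: list = field(default_factory=list)
    outcome_names: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    @property
    def n_features(self) -> int:
        return self.weights.shape[0]

    def coefficients(self, n_components: int | None = None) -> np.ndarray:
        """B = R Qᵀ (p × m) on the autoscaled space, truncated to
        ``n_components`` leading components."""
        a = self.n_components if n_components is None else int(n_components)
        if not 1 <= a <= self.n_components:
            raise ValueError(
                f"n_components must be in [1, {self.n_components}], got {a}"
            )
        return self.weights[:, :a] @ self.y_loadings[:, :a].T


def _autoscale(arr: np.ndarray, center: bool, scale: bool):
    mean = arr.mean(axis=0) if center else np.zeros(arr.shape[1])
    sd = arr.std(axis=0, ddof=1) if scale else np.ones(arr.shape[1])
    if scale and (sd == 0).any():
        raise ValueError(
            f"zero-variance columns at positions {np.flatnonzero(sd == 0)[:5]}"
        )
    return (arr - mean) / sd, mean, sd


# ---------------------------------------------------------------------------
# SIMPLS
# ---------------------------------------------------------------------------

def fit_simpls(X: np.ndarray, Y: np.ndarray, n_components: int):
    """Core SIMPLS on already centered/scaled arrays.

    Returns ``(R, P, Q, T, x_var, y_var)`` with unit-norm score columns.
    The sign of each weight vector is fixed so its largest-magnitude entry
    is positive, which removes the SVD sign ambiguity and makes fits
    bit-reproducible.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    m = Y.shape[1]
    a_max = min(n - 1, p)
    if not 1 <= n_components <= a_max:
        raise ValueError(
            f"n_components must be in [1, min(n-1, p)] = [1, {a_max}], "
            f"got {n_components}"
        )
    S = X.T @ Y
    if not np.any(S):
        raise ValueError("degenerate problem: X'Y is identically zero")
    A = n_components
    R = np.zeros((p, A))
    P = np.zeros((p, A))
    Q = np.zeros((m, A))
    T = np.zeros((n, A))
    V = np.zeros((p, A))
    x_ss = np.sum(X * X)
    y_ss = np.sum(Y * Y)
    x_var = np.zeros(A)
    y_var = np.zeros(A)
    s_ref = None
    x_norm = np.sqrt(x_ss)
    for a in range(A):
        U, sv, _ = np.linalg.svd(S, full_matrices=False)
        if s_ref is None:
            s_ref = sv[0]
        if sv[0] <= 1e-12 * s_ref:
            raise ValueError(
                f"degenerate component {a + 1}: residual X'Y is numerically "
                "zero (X rank or Y structure exhausted)"
            )
        r = U[:, 0]
        r = r * np.sign(r[np.argmax(np.abs(r))])
        t = X @ r
        t_norm = np.linalg.norm(t)
        if t_norm <= 1e-12 * x_norm:
            raise ValueError(
                f"degenerate component {a + 1}: score vector has zero norm"
            )
        t = t / t_norm
        r = r / t_norm
        pvec = X.T @ t
        qvec = Y.T @ t
        v = pvec.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ pvec)
        v_norm = np.linalg.norm(v)
        if v_norm <= np.finfo(float).eps:
            raise ValueError(
                f"degenerate component {a + 1}: loading already spanned"
            )
        v = v / v_norm
        S = S - v[:, None] @ (v[None, :] @ S)
        R[:, a], P[:, a], Q[:, a], T[:, a], V[:, a] = r, pvec, qvec, t, v
        x_var[a] = (pvec @ pvec) / x_ss
        y_var[a] = (qvec @ qvec) / y_ss
    return R, P, Q, T, x_var, y_var


def train_pls(
    X, Y, n_components: int, *, center: bool = True, scale: bool = True
) -> PLSModel:
    """Autoscale X and Y, fit SIMPLS, and package the model.

    ``X`` is the raw-scale predictor matrix (for this pipeline: log10
    abundances) and ``Y`` the raw uptake outcomes; both are mean-centered
    and unit-variance scaled (n−1) before the fit, and the vectors are
    stored on the model.
    """
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else []
    outcome_names = list(Y.columns) if isinstance(Y, pd.DataFrame) else []
    Xa = np.asarray(X, dtype=float)
    Ya = np.asarray(Y, dtype=float)
    if Ya.ndim == 1:
        Ya = Ya[:, None]
    if Xa.shape[0] != Ya.shape[0]:
        raise ValueError("X and Y have different numbers of samples")
    Xs, x_center, x_scale = _autoscale(Xa, center, scale)
    Ys, y_center, y_scale = _autoscale(Ya, center, scale)
    R, P, Q, T, x_var, y_var = fit_simpls(Xs, Ys, n_components)
    return PLSModel(
        weights=R, x_loadings=P, y_loadings=Q, scores=T,
        x_variance_explained=x_var, y_variance_explained=y_var,
        x_center=x_center, x_scale=x_scale,
        y_center=y_center, y_scale=y_scale,
        feature_names=feature_names, outcome_names=outcome_names,
    )


def _check_features(model: PLSModel, X) -> np.ndarray:
    if isinstance(X, pd.DataFrame) and model.feature_names:
        missing = [f for f in model.feature_names if f not in X.columns]
        extra = [f for f in X.columns if f not in model.feature_names]
        if missing or extra:
            raise ValueError(
                f"feature mismatch: missing {missing[:5]}, extra {extra[:5]}"
            )
        X = X[model.feature_names]
    arr = np.asarray(X, dtype=float)
    if arr.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {arr.shape[1]}"
        )
    return arr


def predict(model: PLSModel, X_new, n_components: int | None = None):
    """Predict outcomes for raw-scale ``X_new`` on the raw outcome scale."""
    arr = _check_features(model, X_new)
    Xs = (arr - model.x_center) / model.x_scale
    B = model.coefficients(n_components)
    Yhat = Xs @ B * model.y_scale + model.y_center
    if isinstance(X_new, pd.DataFrame) and model.outcome_names:
        return pd.DataFrame(Yhat, index=X_new.index,
                            columns=model.outcome_names)
    return Yhat


# ---------------------------------------------------------------------------
# VIP
# ---------------------------------------------------------------------------

@dataclass
class VIPResult:
    """Per-outcome and outcome-averaged variable importance in projection."""

    per_outcome: pd.DataFrame   # features × outcomes
    average: pd.Series          # per-feature mean over outcomes
    selected: pd.Index          # features with average strictly > threshold
    threshold: float


def vip_scores(model: PLSModel, threshold: float = 1.0) -> VIPResult:
    """VIP scores per outcome plus the outcome-averaged selection.

    Selection is strict: a feature whose average VIP equals the threshold
    exactly is *not* selected.
    """
    R, Q, T = model.weights, model.y_loadings, model.scores
    p, A = R.shape
    tt = np.einsum("na,na->a", T, T)               # tₐᵀtₐ (=1 here)
    w_norm2 = np.einsum("ja,ja->a", R, R)
    ss = (Q ** 2) * tt[None, :]                    # outcomes × A
    total = ss.sum(axis=1)
    if np.any(total <= 0):
        bad = np.flatnonzero(total <= 0).tolist()
        raise ValueError(f"zero explained sum of squares for outcome(s) {bad}")
    frac = (R ** 2) / w_norm2[None, :]             # p × A
    vip = np.sqrt(p * (frac @ ss.T) / total[None, :])   # p × outcomes
    features = (model.feature_names
                or [f"feature_{j}" for j in range(p)])
    outcomes = (model.outcome_names
                or [f"outcome_{k}" for k in range(Q.shape[0])])
    per_outcome = pd.DataFrame(vip, index=pd.Index(features), columns=outcomes)
    average = per_outcome.mean(axis=1)
    selected = average.index[average > threshold]
    return VIPResult(per_outcome=per_outcome, average=average,
                     selected=selected, threshold=threshold)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Leave-one-out cross-validation summary, on the raw outcome scale."""

    press: pd.Series          # per-outcome predicted residual SS
    rmse: pd.Series           # sqrt(PRESS / n)
    r2: pd.Series             # 1 − PRESS / TSS about the training mean
    predictions: pd.DataFrame  # out-of-fold predictions, samples × outcomes


def loo_cv(
    X, Y, n_components: int, *, rescale_within_fold: bool = False
) -> CVResult:
    """Leave-one-out cross-validation of a SIMPLS fit.

    By default X and Y are autoscaled once on the full training set and the
    folds reuse those vectors (the transform is part of the frozen
    preprocessing; note this shares fold-out means/SDs across folds).
    ``rescale_within_fold=True`` re-autoscales inside each fold instead.
    """
    Xa = np.asarray(X, dtype=float)
    Ya = np.asarray(Y, dtype=float)
    if Ya.ndim == 1:
        Ya = Ya[:, None]
    n = Xa.shape[0]
    if n < 3:
        raise ValueError(f"leave-one-out requires n >= 3, got {n}")
    if n_components >= n - 1:
        raise ValueError(
            f"n_components must be < n-1 = {n - 1} for leave-one-out, "
            f"got {n_components}"
        )
    outcome_names = (list(Y.columns) if isinstance(Y, pd.DataFrame)
                     else [f"outcome_{k}" for k in range(Ya.shape[1])])
    index = (Y.index if isinstance(Y, pd.DataFrame)
             else pd.RangeIndex(n))
    if not rescale_within_fold:
        Xs, _, _ = _autoscale(Xa, True, True)
        Ys, y_center, y_scale = _autoscale(Ya, True, True)
    preds = np.zeros_like(Ya)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[:] = True
        mask[i] = False
        if rescale_within_fold:
            Xf, xc, xs = _autoscale(Xa[mask], True, True)
            Yf, yc, ys = _autoscale(Ya[mask], True, True)
            R, P, Q, T, _, _ = fit_simpls(Xf, Yf, n_components)
            B = R @ Q.T
            preds[i] = ((Xa[i] - xc) / xs) @ B * ys + yc
        else:
            R, P, Q, T, _, _ = fit_simpls(Xs[mask], Ys[mask], n_components)
            B = R @ Q.T
            preds[i] = Xs[i] @ B * y_scale + y_center
    press = ((Ya - preds) ** 2).sum(axis=0)
    tss = ((Ya - Ya.mean(axis=0)) ** 2).sum(axis=0)
    rmse = np.sqrt(press / n)
    r2 = 1.0 - press / tss
    return CVResult(
        press=pd.Series(press, index=outcome_names),
        rmse=pd.Series(rmse, index=outcome_names),
        r2=pd.Series(r2, index=outcome_names),
        predictions=pd.DataFrame(preds, index=index, columns=outcome_names),
    )


# ---------------------------------------------------------------------------
# VIP-based model reduction and held-out evaluation
# ---------------------------------------------------------------------------

@dataclass
class PLSReduction:
    """Artifacts of the full→reduced modelling procedure."""

    full_model: PLSModel
    vip: VIPResult
    reduced_model: PLSModel
    cv_full: CVResult
    cv_reduced: CVResult


def reduce_by_vip(
    X, Y,
    full_components: int = 3,
    reduced_components: int = 2,
    threshold: float = 1.0,
) -> PLSReduction:
    """Fit the full model, select features with mean VIP > threshold, refit.

    The full ``full_components``-component model (all features) and the
    reduced ``reduced_components``-component model (selected features only)
    are each assessed by leave-one-out cross-validation.
    """
    full_model = train_pls(X, Y, full_components)
    cv_full = loo_cv(X, Y, full_components)
    vip = vip_scores(full_model, threshold=threshold)
    if len(vip.selected) == 0:
        raise ValueError(
            f"no features with average VIP > {threshold}; nothing to reduce to"
        )
    X_red = (X[vip.selected] if isinstance(X, pd.DataFrame)
             else np.asarray(X)[:, vip.average.to_numpy() > threshold])
    reduced_model = train_pls(X_red, Y, reduced_components)
    cv_reduced = loo_cv(X_red, Y, reduced_components)
    return PLSReduction(full_model=full_model, vip=vip,
                        reduced_model=reduced_model,
                        cv_full=cv_full, cv_reduced=cv_reduced)


def evaluate_test(model: PLSModel, X_test, Y_test) -> pd.DataFrame:
    """Held-out evaluation: per-outcome R² and RMSE, plus a pooled row.

    R² = 1 − Σ(y−ŷ)² / Σ(y−ȳ_test)², with the test-set mean as baseline;
    the pooled row aggregates residuals across all outcomes.
    """
    Yhat = predict(model, X_test)
    Ya = np.asarray(Y_test, dtype=float)
    Pa = np.asarray(Yhat, dtype=float)
    if Ya.ndim == 1:
        Ya, Pa = Ya[:, None], Pa.reshape(len(Ya), -1)
    rss = ((Ya - Pa) ** 2).sum(axis=0)
    tss = ((Ya - Ya.mean(axis=0)) ** 2).sum(axis=0)
    r2 = 1.0 - rss / tss
    rmse = np.sqrt(rss / Ya.shape[0])
    outcomes = (list(Y_test.columns) if isinstance(Y_test, pd.DataFrame)
                else [f"outcome_{k}" for k in range(Ya.shape[1])])
    out = pd.DataFrame({"r2": r2, "rmse": rmse}, index=outcomes)
    pooled_r2 = 1.0 - rss.sum() / tss.sum()
    pooled_rmse = float(np.sqrt(((Ya - Pa) ** 2).mean()))
    out.loc["pooled"] = [pooled_r2, pooled_rmse]
    return out
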