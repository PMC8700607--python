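"""From-scratch PCA and NIPALS PLS with venetian-blind cross-validation.

The numerical engine of the pipeline.  PLS is the classical NIPALS
algorithm with X- and Y-deflation; latent-variable (LV) count is chosen
as the first important minimum of the cross-validation error curve,
operationalized as the smallest count whose RMSECV is within a small
relative tolerance of the best later value.

Estimators follow scikit-learn conventions (fit/predict, trailing
underscore attributes, get_params/set_params); scikit-learn's own PLS
and PCA serve only as independent oracles in the test suite.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .preprocess import apply_autoscale, autoscale

#: module-level bookkeeping: number of NIPALS fits performed
N_PLS_FITS = 0


# ---------------------------------------------------------------------------
# PCA


class Pca(BaseEstimator):
    """Principal component analysis of an already-autoscaled matrix.

    Computed by singular-value decomposition: loadings are the leading
    right singular vectors (orthonormal), scores the projections, and
    the explained-variance fractions the squared singular values over
    the total sum of squares.  No centering or scaling is applied here;
    the caller autoscales first, as the pipeline does.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("PCA needs a 2-D matrix with at least two rows")
        k = self.n_components if self.n_components is not None else min(X.shape)
        if k > min(X.shape):
            raise ValueError("n_components exceeds matrix rank bound")
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        # sign convention: largest-|.| loading element positive
        for j in range(Vt.shape[0]):
            i = int(np.argmax(np.abs(Vt[j])))
            if Vt[j, i] < 0:
                Vt[j] *= -1.0
                U[:, j] *= -1.0
        total = float(np.sum(s**2))
        self.loadings_ = Vt[:k].T
        self.scores_ = U[:, :k] * s[:k]
        self.singular_values_ = s[:k]
        self.explained_variance_ratio_ = (
            s[:k] ** 2 / total if total > 0 else np.zeros(k)
        )
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float) @ self.loadings_

    def fit_transform(self, X, y=None):
        return self.fit(X).scores_


def pca_fit(matrix: np.ndarray, n_components: int | None = None) -> Pca:
    return Pca(n_components).fit(matrix)


# ---------------------------------------------------------------------------
# NIPALS PLS


class NipalsPls(RegressorMixin, BaseEstimator):
    """NIPALS partial least squares regression.

    Fits ``n_components`` latent variables by the iterative NIPALS
    scheme with deflation of both X and Y.  With ``scale=True`` (the
    default, matching the pipeline's autoscaling) X columns are
    mean-centered and unit-variance scaled and Y is mean-centered using
    training moments only; ``predict`` re-applies those moments.

    Fitted attributes: ``x_weights_`` (p x A), ``x_loadings_`` (p x A),
    ``y_loadings_`` (m x A), ``x_scores_`` (n x A), ``coef_`` (p x m,
    in autoscaled-X space), plus the stored scaling moments.
    """

    def __init__(
        self,
        n_components: int = 2,
        scale: bool = True,
        tol: float = 1e-10,
        max_iter: int = 500,
    ):
        self.n_components = n_components
        self.scale = scale
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, Y):
        global N_PLS_FITS
        N_PLS_FITS += 1
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
            self._y_1d = True
        else:
            self._y_1d = False
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y row counts differ")
        if self.n_components > min(X.shape):
            raise ValueError("n_components exceeds min(n_samples, n_features)")
        if self.scale:
            Xc, self.x_mean_, self.x_std_ = autoscale(X)
            self.y_mean_ = Y.mean(axis=0)
            Yc = Y - self.y_mean_
        else:
            self.x_mean_ = np.zeros(X.shape[1])
            self.x_std_ = np.ones(X.shape[1])
            self.y_mean_ = np.zeros(Y.shape[1])
            Xc, Yc = X.copy(), Y.copy()
        if np.all(Y.std(axis=0) < 1e-12):
            raise ValueError("Y has zero variance")

        n, p = Xc.shape
        m = Yc.shape[1]
        W = np.zeros((p, self.n_components))
        P = np.zeros((p, self.n_components))
        Q = np.zeros((m, self.n_components))
        T = np.zeros((n, self.n_components))
        Xr, Yr = Xc.copy(), Yc.copy()
        n_found = 0
        for a in range(self.n_components):
            u = Yr[:, int(np.argmax(Yr.var(axis=0)))]
            if float(np.linalg.norm(Xr)) < 1e-12 or float(np.linalg.norm(u)) < 1e-12:
                break  # X or Y residual exhausted; keep the LVs found
            t_old = None
            for _ in range(self.max_iter):
                w = Xr.T @ u
                nw = np.linalg.norm(w)
                if nw < 1e-14:
                    break
                w = w / nw
                t = Xr @ w
                tt = float(t @ t)
                q = Yr.T @ t / tt
                if m == 1:
                    t_old = t
                    break
                u = Yr @ q / float(q @ q)
                if t_old is not None and np.linalg.norm(t - t_old) <= self.tol * max(
                    np.linalg.norm(t), 1e-30
                ):
                    t_old = t
                    break
                t_old = t
            else:
                raise RuntimeError(
                    f"NIPALS did not converge for latent variable {a + 1}"
                )
            t = t_old
            if t is None or float(t @ t) < 1e-24:
                break
            # sign convention: largest-|.| weight element positive
            i = int(np.argmax(np.abs(w)))
            if w[i] < 0:
                w, t = -w, -t
            tt = float(t @ t)
            p_vec = Xr.T @ t / tt
            q = Yr.T @ t / tt
            W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_vec, q, t
            Xr = Xr - np.outer(t, p_vec)
            Yr = Yr - np.outer(t, q)
            n_found += 1

        self.n_components_ = n_found
        self.x_weights_ = W[:, :n_found]
        self.x_loadings_ = P[:, :n_found]
        self.y_loadings_ = Q[:, :n_found]
        self.x_scores_ = T[:, :n_found]
        if n_found:
            R = self.x_weights_ @ np.linalg.inv(
                self.x_loadings_.T @ self.x_weights_
            )
        else:
            R = np.zeros((p, 0))
        self.x_rotations_ = R
        self.coef_ = R @ self.y_loadings_.T
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.coef_.shape[0]:
            raise ValueError("X_new column count does not match training variables")
        Xs = apply_autoscale(X, self.x_mean_, self.x_std_)
        Yh = Xs @ self.coef_ + self.y_mean_
        return Yh[:, 0] if self._y_1d else Yh

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        Xs = apply_autoscale(X, self.x_mean_, self.x_std_)
        return Xs @ self.x_rotations_


def pls_fit(X, Y, n_lv: int, scale: bool = True) -> NipalsPls:
    return NipalsPls(n_components=n_lv, scale=scale).fit(X, Y)


def pls_predict(model: NipalsPls, X_new):
    return model.predict(X_new)


# ---------------------------------------------------------------------------
# cross-validation


def venetian_blind_splits(n_samples: int, n_splits: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Interleaved CV folds: test split k holds samples k, k+n_splits, ...

    The test sets partition the sample index set; with
    n_splits == n_samples this is leave-one-out.
    """
    if not (2 <= n_splits <= n_samples):
        raise ValueError("need 2 <= n_splits <= n_samples")
    all_idx = np.arange(n_samples)
    splits = []
    for k in range(n_splits):
        test = all_idx[k::n_splits]
        train = np.setdiff1d(all_idx, test)
        splits.append((train, test))
    return splits


@dataclass
class CVResult:
    rmsecv_by_lv: np.ndarray
    chosen_lv: int
    n_fits: int = 0


def select_lv(rmsecv_by_lv, rel_tol: float = 0.02) -> int:
    """First-important-minimum rule on an error-versus-LV curve.

    Returns the smallest LV count whose error is within ``rel_tol`` of
    the best error achieved by any *larger* count; if no later count
    beats it, the argmin.  LV counts are 1-based.
    """
    r = np.asarray(rmsecv_by_lv, dtype=float)
    if r.size == 0:
        raise ValueError("empty error curve")
    for L in range(r.size - 1):
        if r[L] <= (1.0 + rel_tol) * float(np.min(r[L + 1 :])):
            return L + 1
    return int(np.argmin(r)) + 1


def cross_validate_pls(
    X,
    Y,
    max_lv: int,
    n_splits: int = 10,
    rel_tol: float = 0.02,
) -> CVResult:
    """Venetian-blind RMSECV per LV count; every fold is scaled on its
    training rows only (the PLS estimator stores training moments)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if max_lv < 1:
        raise ValueError("max_lv must be at least 1")
    n = X.shape[0]
    n_splits = min(n_splits, n)
    splits = venetian_blind_splits(n, n_splits)
    for train, _ in splits:
        if train.size < 2:
            raise ValueError("a fold has fewer than two training rows")
    global N_PLS_FITS
    fits_before = N_PLS_FITS
    sq = np.zeros(max_lv)
    count = 0
    for train, test in splits:
        for a in range(1, max_lv + 1):
            model = NipalsPls(n_components=min(a, min(train.size, X.shape[1]))).fit(
                X[train], Y[train]
            )
            resid = np.asarray(Y[test]) - np.asarray(model.predict(X[test]))
            sq[a - 1] += float(np.sum(resid**2))
        count += np.asarray(Y[test]).size
    rmsecv = np.sqrt(sq / count)
    return CVResult(
        rmsecv_by_lv=rmsecv,
        chosen_lv=select_lv(rmsecv, rel_tol),
        n_fits=N_PLS_FITS - fits_before,
    )


# ---------------------------------------------------------------------------
# serialization


def model_to_json(model: NipalsPls) -> str:
    """Serialize a fitted PLS model to a versioned JSON document."""
    doc = {
        "schema": "teafp.pls/1",
        "n_components": model.n_components_,
        "x_weights": model.x_weights_.tolist(),
        "x_loadings": model.x_loadings_.tolist(),
        "y_loadings": model.y_loadings_.tolist(),
        "coef": model.coef_.tolist(),
        "x_mean": model.x_mean_.tolist(),
        "x_std": model.x_std_.tolist(),
        "y_mean": np.asarray(model.y_mean_).tolist(),
        "y_1d": model._y_1d,
    }
    return json.dumps(doc)


def model_from_json(doc: str) -> NipalsPls:
    d = json.loads(doc)
    if d.get("schema") != "teafp.pls/1":
        raise ValueError("unknown model schema")
    model = NipalsPls(n_components=d["n_components"])
    model.n_components_ = d["n_components"]
    model.x_weights_ = np.asarray(d["x_weights"])
    model.x_loadings_ = np.asarray(d["x_loadings"])
    model.y_loadings_ = np.asarray(d["y_loadings"])
    model.coef_ = np.asarray(d["coef"])
    model.x_mean_ = np.asarray(d["x_mean"])
    model.x_std_ = np.asarray(d["x_std"])
    model.y_mean_ = np.asarray(d["y_mean"])
    model._y_1d = d["y_1d"]
    if model.n_components_:
        model.x_rotations_ = model.x_weights_ @ np.linalg.inv(
            model.x_loadings_.T @ model.x_weights_
        )
    else:
        model.x_rotations_ = np.zeros((model.coef_.shape[0], 0))
    model.x_scores_ = np.zeros((0, model.n_components_))
    return model
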