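"""Column scaling, PCA, and orthogonal PLS (OPLS-DA) estimators.

Scaling offers mean centering, Pareto scaling (sqrt of the column sd),
autoscaling (unit variance), and class-centroid centering/scaling for
unequal class sizes — offset (x̄A + x̄B)/2 and pooled standard deviation —
so that the class boundary is not dragged toward the larger group.

The OPLS filter splits the systematic variation of X into a single
Y-predictive component, a set of Y-orthogonal components ("structured
noise"), and residual variance.  With one predictive plus k orthogonal
components its fitted values coincide with those of a plain PLS1 model
with k+1 components; the decomposition only reapportions the variance so
the class-predictive direction is interpretable on its own.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin

CASE_LABEL = "Schizophrenia"

SCALING_METHODS = ("center", "pareto", "auto", "class_centroid")


def encode_classes(labels) -> tuple[np.ndarray, tuple[str, str]]:
    """Map a two-class label vector to {0, 1}.

    The case class ('Schizophrenia' when present, otherwise the
    lexicographically larger label) is coded 1.
    """
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    if CASE_LABEL in classes:
        neg = classes[0] if classes[1] == CASE_LABEL else classes[1]
        pos = CASE_LABEL
    else:
        neg, pos = classes
    return (labels == pos).astype(float), (neg, pos)


class ColumnScaler(BaseEstimator, TransformerMixin):
    """Column centering/scaling with four methods.

    center: offset = column mean, scale 1.  pareto: scale = sqrt(sd).
    auto: scale = sd.  class_centroid: offset = (x̄A + x̄B)/2, scale =
    pooled sd (requires labels).  Columns with zero variance under a
    variance-based method are dropped with a warning and recorded in
    ``dropped_columns_``.
    """

    def __init__(self, method: str = "auto"):
        self.method = method

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.method not in SCALING_METHODS:
            raise ValueError(f"unknown scaling method {self.method!r}")
        p = X.shape[1]
        self.class_means_ = None
        self.pooled_sd_ = None

        if self.method == "class_centroid":
            if y is None:
                raise ValueError("class_centroid scaling requires class labels")
            y = np.asarray(y)
            classes = sorted(set(y.tolist()))
            if len(classes) != 2:
                raise ValueError("class_centroid scaling needs exactly two classes")
            A, B = (X[y == c] for c in classes)
            if len(A) < 2 or len(B) < 2:
                raise ValueError("need at least 2 samples per class")
            mA, mB = A.mean(axis=0), B.mean(axis=0)
            self.class_means_ = (mA, mB)
            offset = 0.5 * (mA + mB)
            pooled = np.sqrt(
                ((len(A) - 1) * A.var(axis=0, ddof=1) + (len(B) - 1) * B.var(axis=0, ddof=1))
                / (len(A) + len(B) - 2)
            )
            self.pooled_sd_ = pooled
            scale = pooled
        else:
            offset = X.mean(axis=0)
            if self.method == "center":
                scale = np.ones(p)
            else:
                sd = X.std(axis=0, ddof=1)
                scale = np.sqrt(sd) if self.method == "pareto" else sd

        dropped = np.flatnonzero(scale == 0)
        if dropped.size:
            warnings.warn(
                f"{dropped.size} zero-variance column(s) dropped under "
                f"{self.method} scaling",
                stacklevel=2,
            )
        self.dropped_columns_ = dropped
        keep = np.ones(p, dtype=bool)
        keep[dropped] = False
        self.keep_mask_ = keep
        self.offsets_ = offset
        self.scales_ = np.where(keep, scale, 1.0)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        Z = (X - self.offsets_) / self.scales_
        return Z[:, self.keep_mask_]

    def inverse_transform(self, Z):
        Z = np.asarray(Z, dtype=float)
        out = np.tile(self.offsets_, (Z.shape[0], 1))
        out[:, self.keep_mask_] += Z * self.scales_[self.keep_mask_]
        return out


def fit_scaling(X, method: str = "auto", labels=None) -> ColumnScaler:
    """Thin functional wrapper over :class:`ColumnScaler`."""
    return ColumnScaler(method=method).fit(X, labels)


class PCASpectra(BaseEstimator, TransformerMixin):
    """PCA of an already-scaled matrix via singular value decomposition.

    Component k's variance fraction is σk²/Σσ² over all singular values.
    If ``n_components`` exceeds the matrix rank the trailing components are
    kept but flagged in ``zero_variance_components_``.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        k = self.n_components
        if k > min(n - 1, p):
            raise ValueError("n_components must be <= min(n_samples - 1, n_variables)")
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        total = (s**2).sum()
        self.singular_values_ = s[:k]
        self.loadings_ = Vt[:k].T  # P x K, column-orthonormal
        self.scores_ = U[:, :k] * s[:k]
        frac = s[:k] ** 2 / total if total > 0 else np.zeros(k)
        self.explained_variance_fraction_ = frac
        self.cumulative_variance_fraction_ = np.cumsum(frac)
        tol = s[0] * max(n, p) * np.finfo(float).eps if s.size else 0.0
        self.zero_variance_components_ = np.flatnonzero(s[:k] <= tol)
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float) @ self.loadings_


def pca_fit(Xs, n_components: int = 2) -> PCASpectra:
    return PCASpectra(n_components=n_components).fit(Xs)


class OPLS(BaseEstimator, RegressorMixin):
    """Orthogonal PLS with one predictive component (two-class response).

    Fitting iteratively extracts Y-orthogonal components — w_o ∝
    p − (w'p)w, with scores t_o = X·w_o and loadings p_o — deflating X by
    t_o·p_o' each round, then computes the predictive component (w, t, p)
    and the Y loading q on the filtered matrix.  Extraction stops early if
    an orthogonal score norm falls below ``tol`` times the matrix norm; the
    count actually extracted is ``n_orthogonal_effective_``.
    """

    def __init__(self, n_orthogonal: int = 1, tol: float = 1e-12):
        self.n_orthogonal = n_orthogonal
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.size:
            raise ValueError("X and y disagree on the number of samples")
        if self.n_orthogonal < 0:
            raise ValueError("n_orthogonal must be >= 0")
        self.y_mean_ = float(y.mean())
        yc = y - self.y_mean_
        x_norm = np.linalg.norm(X)
        total_ss = x_norm**2

        w = X.T @ yc
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError("X carries no covariance with y")
        w = w / nw

        Xd = X.copy()
        W_o, T_o, P_o = [], [], []
        orth_var = []
        for _ in range(self.n_orthogonal):
            t = Xd @ w
            p = Xd.T @ t / (t @ t)
            w_o = p - (w @ p) * w
            n_wo = np.linalg.norm(w_o)
            if n_wo <= self.tol * max(x_norm, 1.0):
                break
            w_o = w_o / n_wo
            t_o = Xd @ w_o
            if np.linalg.norm(t_o) <= self.tol * max(x_norm, 1.0):
                break
            p_o = Xd.T @ t_o / (t_o @ t_o)
            Xd = Xd - np.outer(t_o, p_o)
            W_o.append(w_o)
            T_o.append(t_o)
            P_o.append(p_o)
            orth_var.append(float((t_o @ t_o) * (p_o @ p_o)))

        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        q = float(yc @ t / (t @ t))

        self.w_ = w
        self.t_ = t
        self.p_ = p
        self.q_ = q
        self.W_o_ = np.array(W_o).T if W_o else np.zeros((X.shape[1], 0))
        self.T_o_ = np.array(T_o).T if T_o else np.zeros((X.shape[0], 0))
        self.P_o_ = np.array(P_o).T if P_o else np.zeros((X.shape[1], 0))
        self.n_orthogonal_effective_ = len(W_o)

        # direct-prediction coefficient vector: b = q · M1···Mk w with
        # Mj = I − w_oj p_oj' applied innermost-first
        v = w.copy()
        for j in reversed(range(len(W_o))):
            v = v - W_o[j] * (P_o[j] @ v)
        self.b_ = q * v

        pred_var = float((t @ t) * (p @ p))
        self.explained_variance_ = {
            "predictive": pred_var / total_ss if total_ss else 0.0,
            "orthogonal": [v_ / total_ss for v_ in orth_var] if total_ss else [],
            "total": (pred_var + sum(orth_var)) / total_ss if total_ss else 0.0,
        }
        self.fitted_values_ = t * q + self.y_mean_
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.w_.size:
            raise ValueError("column count mismatch with the fitted model")
        return X @ self.b_ + self.y_mean_

    def predictive_scores(self, X) -> np.ndarray:
        """Orthogonal-filtered predictive scores t for new data."""
        Xf = np.asarray(X, dtype=float).copy()
        for j in range(self.n_orthogonal_effective_):
            t_o = Xf @ self.W_o_[:, j]
            Xf = Xf - np.outer(t_o, self.P_o_[:, j])
        return Xf @ self.w_


def opls_fit(Xs, y, n_orth: int = 1) -> OPLS:
    return OPLS(n_orthogonal=n_orth).fit(Xs, y)


def opls_predict(model: OPLS, X_scaled) -> np.ndarray:
    return model.predict(X_scaled)


def backscale_loadings(
    model: OPLS, scaling: ColumnScaler, Xs
) -> tuple[np.ndarray, np.ndarray]:
    """Back-scale the predictive loading and compute correlation weights.

    The back-scaled loading (predictive loading x column scale) resembles a
    spectrum again; the weight for variable i is |corr(Xs_i, t)|, used as a
    color code for the relative importance of variables.
    """
    Xs = np.asarray(Xs, dtype=float)
    scales = scaling.scales_[scaling.keep_mask_]
    backscaled = model.p_ * scales
    t = model.t_
    tc = t - t.mean()
    Xc = Xs - Xs.mean(axis=0)
    denom = np.linalg.norm(Xc, axis=0) * np.linalg.norm(tc)
    with np.errstate(invalid="ignore", divide="ignore"):
        weights = np.abs(Xc.T @ tc) / denom
    weights = np.where(denom > 0, weights, 0.0)
    return backscaled, weights


# ----------------------------------------------------------------------
# serialization: a portable key-value container (JSON) so fitted models can
# be handed between pipeline stages and CLI invocations


def _encode(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def save_model(path: str | Path, model: OPLS, scaler: ColumnScaler | None = None) -> None:
    """Write a fitted OPLS model (and optionally its scaler) to JSON."""
    payload = {
        "model": {
            "n_orthogonal": model.n_orthogonal,
            "w": model.w_, "t": model.t_, "p": model.p_, "q": model.q_,
            "W_o": model.W_o_, "T_o": model.T_o_, "P_o": model.P_o_,
            "b": model.b_, "y_mean": model.y_mean_,
            "n_orthogonal_effective": model.n_orthogonal_effective_,
            "explained_variance": model.explained_variance_,
            "fitted_values": model.fitted_values_,
        }
    }
    if scaler is not None:
        payload["scaler"] = {
            "method": scaler.method,
            "offsets": scaler.offsets_, "scales": scaler.scales_,
            "keep_mask": scaler.keep_mask_.astype(int),
            "dropped_columns": scaler.dropped_columns_,
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, default=_encode)


def load_model(path: str | Path) -> tuple[OPLS, ColumnScaler | None]:
    """Read a model (and scaler, if present) written by :func:`save_model`."""
    with open(path) as fh:
        payload = json.load(fh)
    m = payload["model"]
    model = OPLS(n_orthogonal=m["n_orthogonal"])
    model.w_ = np.asarray(m["w"])
    model.t_ = np.asarray(m["t"])
    model.p_ = np.asarray(m["p"])
    model.q_ = float(m["q"])
    model.W_o_ = np.asarray(m["W_o"]).reshape(len(m["w"]), -1)
    model.T_o_ = np.asarray(m["T_o"]).reshape(len(m["t"]), -1)
    model.P_o_ = np.asarray(m["P_o"]).reshape(len(m["w"]), -1)
    model.b_ = np.asarray(m["b"])
    model.y_mean_ = float(m["y_mean"])
    model.n_orthogonal_effective_ = int(m["n_orthogonal_effective"])
    model.explained_variance_ = m["explained_variance"]
    model.fitted_values_ = np.asarray(m["fitted_values"])
    scaler = None
    if "scaler" in payload:
        sc = payload["scaler"]
        scaler = ColumnScaler(method=sc["method"])
        scaler.offsets_ = np.asarray(sc["offsets"])
        scaler.scales_ = np.asarray(sc["scales"])
        scaler.keep_mask_ = np.asarray(sc["keep_mask"], dtype=bool)
        scaler.dropped_columns_ = np.asarray(sc["dropped_columns"], dtype=int)
        scaler.class_means_ = None
        scaler.pooled_sd_ = None
    return model, scaler
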