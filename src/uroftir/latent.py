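"""Orthogonal projections to latent structures (OPLS) and PLS evaluation.

OPLS splits the predictor variation into a part correlated with the class
label and parts orthogonal to it, and removes the orthogonal parts before
predictive modelling.  The implementation follows the canonical Trygg-Wold
O-PLS deflation: per orthogonal component

    w   proportional to X'y            (unit predictive weight)
    t   = X w
    p   = X't / (t't)
    w_o proportional to p - (w'p) w    (unit orthogonal weight)
    t_o = X w_o,   p_o = X't_o / (t_o't_o)
    X  <- X - t_o p_o'

repeated ``n_ortho`` times (the study protocol uses 20).  By construction
each orthogonal score vector t_o is orthogonal to the centred response.

The filtered matrix is then assessed with PLS regression (NIPALS, via
scikit-learn) on the 0/1 label, scored by R^2, thresholded accuracy and the
area under the ROC curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import ParameterError, ShapeError, UndefinedMetricError

__all__ = [
    "OplsModel",
    "fit_opls",
    "opls_transform",
    "PlsModel",
    "fit_pls",
    "pls_predict",
    "r2_score",
    "roc_auc",
]

_NORM_TOL = 1e-12


@dataclass
class OplsModel:
    """Fitted orthogonal filter: weights/loadings per orthogonal component."""

    n_ortho: int
    w_ortho: list[np.ndarray] = field(default_factory=list)
    p_ortho: list[np.ndarray] = field(default_factory=list)
    t_ortho: list[np.ndarray] = field(default_factory=list)
    predictive_w: np.ndarray | None = None
    train_mean_x: np.ndarray | None = None
    train_mean_y: float = 0.0
    filtered_train: np.ndarray | None = None

    @property
    def n_components_fitted(self) -> int:
        return len(self.w_ortho)


def fit_opls(X: np.ndarray, y: np.ndarray, n_ortho: int = 20) -> OplsModel:
    """Fit an OPLS orthogonal-variation filter on training data.

    ``X`` and ``y`` are taken raw; the model stores the training column
    means and mean label used for centring.  Extraction stops early (with a
    warning) if no orthogonal variation remains.
    """
    if n_ortho < 0:
        raise ParameterError("n_ortho must be >= 0")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0] or X.shape[0] < 3:
        raise ParameterError("need >= 3 rows and matching y length")

    model = OplsModel(n_ortho=n_ortho)
    model.train_mean_x = X.mean(axis=0)
    model.train_mean_y = float(y.mean())
    Xc = X - model.train_mean_x
    yc = y - model.train_mean_y

    for _ in range(n_ortho):
        w = Xc.T @ yc
        wn = np.linalg.norm(w)
        if wn < _NORM_TOL:
            warnings.warn("no covariance with y left; stopping OPLS early")
            break
        w /= wn
        t = Xc @ w
        p = Xc.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        won = np.linalg.norm(w_o)
        if won < _NORM_TOL * max(1.0, np.linalg.norm(p)):
            warnings.warn(
                f"no orthogonal variation left after {model.n_components_fitted} "
                "components; stopping OPLS early"
            )
            break
        w_o /= won
        t_o = Xc @ w_o
        p_o = Xc.T @ t_o / (t_o @ t_o)
        Xc = Xc - np.outer(t_o, p_o)
        model.w_ortho.append(w_o)
        model.p_ortho.append(p_o)
        model.t_ortho.append(t_o)

    w = Xc.T @ yc
    wn = np.linalg.norm(w)
    model.predictive_w = w / wn if wn > _NORM_TOL else w
    model.filtered_train = Xc
    return model


def opls_transform(model: OplsModel, X_new: np.ndarray) -> np.ndarray:
    """Centre with the training means and strip the orthogonal components.

    Applying the transform to the training matrix reproduces the filtered
    matrix stored at fit time; applying it twice is a no-op beyond the
    first application.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if model.train_mean_x is None or X_new.shape[1] != model.train_mean_x.size:
        raise ShapeError("column count does not match the fitted OPLS model")
    Xc = X_new - model.train_mean_x
    for w_o, p_o in zip(model.w_ortho, model.p_ortho):
        t = Xc @ w_o
        Xc = Xc - np.outer(t, p_o)
    return Xc


@dataclass
class PlsModel:
    """Fitted PLS regression of the 0/1 label on (filtered) spectra."""

    n_components: int
    scores: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    coefficients: np.ndarray
    train_mean_x: np.ndarray
    train_mean_y: float
    _sk: PLSRegression | None = None


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int = 2) -> PlsModel:
    """NIPALS PLS regression on centred data (scikit-learn backend)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_components < 1 or n_components > min(X.shape[0] - 1, X.shape[1]):
        raise ParameterError(
            f"n_components {n_components} outside [1, min(rows-1, cols)]"
        )
    sk = PLSRegression(n_components=n_components, scale=False)
    sk.fit(X, y)
    return PlsModel(
        n_components=n_components,
        scores=sk.x_scores_,
        x_loadings=sk.x_loadings_,
        y_loadings=sk.y_loadings_.ravel(),
        coefficients=sk.coef_.ravel(),
        train_mean_x=X.mean(axis=0),
        train_mean_y=float(np.mean(y)),
        _sk=sk,
    )


def pls_predict(model: PlsModel, X_new: np.ndarray) -> np.ndarray:
    """Continuous decoded scores: centred X_new @ coefficients + mean(y)."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.train_mean_x.size:
        raise ShapeError("column count does not match the fitted PLS model")
    return (X_new - model.train_mean_x) @ model.coefficients + model.train_mean_y


def r2_score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ParameterError("inputs must have equal length >= 2")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedMetricError("R^2 undefined: y_true has zero variance")
    return 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> dict:
    """ROC curve and AUC (Mann-Whitney pair-probability identity).

    Returns ``{"fpr", "tpr", "thresholds", "auc"}``.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUC undefined: single-class labels")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    return {
        "fpr": fpr,
        "tpr": tpr,
        "thresholds": thresholds,
        "auc": float(roc_auc_score(labels, scores)),
    }
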