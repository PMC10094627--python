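"""Supervised PLS-DA with NIPALS, cross-validated Q2, VIP scores,
permutation validation and Hotelling's T2 ellipse.

The model regresses a dummy-coded district matrix Y (one column per group)
on the autoscaled concentration matrix X using NIPALS PLS2.  Diagnostics
follow chemometrics conventions:

* ``R2X`` / ``R2Y`` - cumulative fraction of X / Y variance captured by the
  extracted components,
* ``Q2 = 1 - PRESS/SS`` - predictive ability from k-fold cross-validation
  with interleaved ("venetian blind") fold assignment, scaling re-estimated
  inside each training split,
* ``VIP_j = sqrt(p * sum_a ssy_a w_aj^2 / sum_a ssy_a)`` - variable
  importance in projection, with weight vectors normalized to unit length
  so that the VIP scores always satisfy ``sum_j VIP_j^2 = p``,
* SIMCA-style permutation validation - refit the model on label-permuted
  data and regress R2Y and Q2 on the label-correlation statistic; a sound
  model has all permuted Q2 below the original and a negative Q2 intercept.

X is autoscaled (centered, unit variance); Y is centered only.  Unit-variance
scaling of the dummy Y would upweight single-sample districts roughly
12-fold in the default unbalanced design, so it is deliberately not applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ValidationError

__all__ = [
    "Scaler",
    "autoscale",
    "one_hot",
    "PlsdaModel",
    "fit_plsda",
    "cross_validated_q2",
    "compute_vip",
    "PermutationReport",
    "permutation_test",
    "HotellingEllipse",
    "hotelling_ellipse",
]

_TOL = 1e-10
_MAX_ITER = 500


@dataclass
class Scaler:
    """Column mean/SD pair from autoscaling; inverts exactly."""

    mean: np.ndarray
    std: np.ndarray
    zero_variance: np.ndarray  # boolean flag per column

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.std

    def inverse(self, Xs: np.ndarray) -> np.ndarray:
        return np.asarray(Xs, dtype=float) * self.std + self.mean


def autoscale(X: Union[np.ndarray, pd.DataFrame]) -> Tuple[np.ndarray, Scaler]:
    """Center each column and scale to unit sample SD (ddof=1).

    Zero-variance columns are mapped to all-zeros and flagged in the
    returned :class:`Scaler` (their stored SD is 1 so the inverse still
    reproduces the constant).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("autoscale needs a 2-D matrix with at least 2 rows")
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=1)
    zero = std == 0.0
    safe_std = np.where(zero, 1.0, std)
    return (X - mean) / safe_std, Scaler(mean=mean, std=safe_std, zero_variance=zero)


def one_hot(
    groups: Sequence[str], group_labels: Sequence[str]
) -> np.ndarray:
    """Dummy-code group membership: Y[i, g] = 1 iff row i belongs to group g."""
    labels = list(group_labels)
    index = {g: j for j, g in enumerate(labels)}
    unknown = sorted({g for g in groups if g not in index})
    if unknown:
        raise ValidationError(f"labels outside the declared group set: {unknown}")
    Y = np.zeros((len(groups), len(labels)))
    for i, g in enumerate(groups):
        Y[i, index[g]] = 1.0
    return Y


@dataclass
class PlsdaModel:
    """A fitted PLS2 discriminant model.

    Matrix shapes: weights ``W`` and x-loadings ``P`` are (p, A), y-loadings
    ``C`` is (G, A), scores ``T`` is (n, A).  ``ssy`` holds the Y sum of
    squares explained per component; ``r2y`` equals ``ssy.sum()`` divided by
    the total (centered) Y sum of squares.
    """

    n_components: int
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    ssy: np.ndarray
    ssx: np.ndarray
    r2x: float
    r2y: float
    x_scaler: Scaler
    y_mean: np.ndarray
    q2: Optional[float] = None
    feature_names: Optional[Tuple[str, ...]] = None

    @property
    def coefficients(self) -> np.ndarray:
        """Regression coefficients B (p x G) on the scaled scale."""
        W, P, C = self.weights, self.x_loadings, self.y_loadings
        return W @ np.linalg.solve(P.T @ W, C.T)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted (continuous) dummy responses for new raw rows."""
        Xs = self.x_scaler.transform(np.atleast_2d(np.asarray(X, dtype=float)))
        return Xs @ self.coefficients + self.y_mean

    def predict_groups(self, X: np.ndarray, group_labels: Sequence[str]) -> list:
        scores = self.predict(X)
        labels = list(group_labels)
        return [labels[j] for j in np.argmax(scores, axis=1)]


def _nipals_component(X: np.ndarray, Y: np.ndarray):
    """Extract one PLS2 component from (already deflated) X, Y."""
    u = Y[:, np.argmax(Y.var(axis=0))].copy()
    if not np.any(u):
        u = Y[:, 0] + 1e-12
    w = np.zeros(X.shape[1])
    for _ in range(_MAX_ITER):
        w_new = X.T @ u / (u @ u)
        norm = np.linalg.norm(w_new)
        if norm == 0:
            raise ValidationError("NIPALS collapsed: X carries no covariance with Y")
        w_new /= norm
        t = X @ w_new
        c = Y.T @ t / (t @ t)
        u = Y @ c / (c @ c)
        if np.linalg.norm(w_new - w) < _TOL:
            w = w_new
            break
        w = w_new
    t = X @ w
    c = Y.T @ t / (t @ t)
    # sign convention: the largest-magnitude weight is positive
    j = int(np.argmax(np.abs(w)))
    if w[j] < 0:
        w, t, c = -w, -t, -c
    p_load = X.T @ t / (t @ t)
    return w, t, c, p_load


def fit_plsda(
    X: Union[np.ndarray, pd.DataFrame],
    Y: np.ndarray,
    n_components: Union[int, str] = "auto",
    cv_folds: int = 7,
) -> PlsdaModel:
    """Fit a PLS2 discriminant model with NIPALS.

    ``n_components="auto"`` adds components while cross-validated Q2 improves
    by more than 0.01, capped at ``min(10, n - 1, p, G)``.  Fitting is
    deterministic: the NIPALS start vector is the Y column with the largest
    variance, and each weight vector's largest-magnitude element is made
    positive.
    """
    feature_names = None
    if isinstance(X, pd.DataFrame):
        feature_names = tuple(map(str, X.columns))
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    G = Y.shape[1]
    if n < 3:
        raise ValidationError("PLS-DA needs at least 3 rows")

    folds_eff = min(cv_folds, n)
    cap = min(10, n - 1, p, G)
    if n_components == "auto":
        best_a, best_q2 = 1, -np.inf
        for a in range(1, cap + 1):
            q2 = cross_validated_q2(X, Y, a, folds_eff)
            if q2 > best_q2 + 0.01:
                best_a, best_q2 = a, q2
            else:
                break
        A = best_a
    else:
        A = int(n_components)
        if A < 1:
            raise ValidationError("n_components must be at least 1")
        hard_cap = min(n - 1, p)
        if A > hard_cap:
            warnings.warn(
                f"requested {A} components exceeds the data rank bound "
                f"{hard_cap}; truncating",
                stacklevel=2,
            )
            A = hard_cap

    Xs, scaler = autoscale(X)
    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean
    ssx_total = float((Xs**2).sum())
    ssy_total = float((Yc**2).sum())

    Xd, Yd = Xs.copy(), Yc.copy()
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    C = np.zeros((G, A))
    T = np.zeros((n, A))
    ssy = np.zeros(A)
    ssx = np.zeros(A)
    for a in range(A):
        w, t, c, p_load = _nipals_component(Xd, Yd)
        W[:, a], T[:, a], C[:, a], P[:, a] = w, t, c, p_load
        tt = float(t @ t)
        ssy[a] = tt * float(c @ c)
        ssx[a] = tt * float(p_load @ p_load)
        Xd = Xd - np.outer(t, p_load)
        Yd = Yd - np.outer(t, c)

    model = PlsdaModel(
        n_components=A,
        weights=W,
        x_loadings=P,
        y_loadings=C,
        scores=T,
        ssy=ssy,
        ssx=ssx,
        r2x=float(ssx.sum() / ssx_total) if ssx_total > 0 else 0.0,
        r2y=float(ssy.sum() / ssy_total) if ssy_total > 0 else 0.0,
        x_scaler=scaler,
        y_mean=y_mean,
        feature_names=feature_names,
    )
    model.q2 = cross_validated_q2(X, Y, A, folds_eff)
    return model


def _venetian_folds(n: int, folds: int) -> np.ndarray:
    return np.arange(n) % folds


def cross_validated_q2(
    X: np.ndarray, Y: np.ndarray, n_components: int, folds: int
) -> float:
    """Q2 = 1 - PRESS/SS under interleaved k-fold cross-validation.

    Rows ``k, k + folds, k + 2*folds, ...`` form fold ``k``.  Scaling
    parameters and the model are re-estimated on each training split; PRESS
    accumulates squared held-out dummy-response errors, SS the squared
    deviations of held-out responses from the training mean.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if folds < 2:
        raise ValidationError("cross-validation needs at least 2 folds")
    if folds > n:
        raise ValidationError("more folds than rows")
    assignment = _venetian_folds(n, folds)
    press = 0.0
    ss = 0.0
    for k in range(folds):
        test = assignment == k
        train = ~test
        Y_train, Y_test = Y[train], Y[test]
        if (Y_train.sum(axis=0) == 0).any():
            warnings.warn(
                f"fold {k}: at least one class absent from the training split",
                stacklevel=2,
            )
        A = min(n_components, int(train.sum()) - 1, X.shape[1])
        sub = fit_plsda_fixed(X[train], Y_train, A)
        Y_hat = sub.predict(X[test])
        press += float(((Y_test - Y_hat) ** 2).sum())
        ss += float(((Y_test - Y_train.mean(axis=0)) ** 2).sum())
    if ss == 0:
        raise ValidationError("response matrix has zero held-out variance")
    return 1.0 - press / ss


def fit_plsda_fixed(X: np.ndarray, Y: np.ndarray, n_components: int) -> PlsdaModel:
    """Fit at a fixed component count without nested cross-validation."""
    feature_names = None
    if isinstance(X, pd.DataFrame):
        feature_names = tuple(map(str, X.columns))
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    G = Y.shape[1]
    A = min(int(n_components), n - 1, p)
    Xs, scaler = autoscale(X)
    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean
    ssx_total = float((Xs**2).sum())
    ssy_total = float((Yc**2).sum())
    Xd, Yd = Xs.copy(), Yc.copy()
    W, P, C, T = (
        np.zeros((p, A)),
        np.zeros((p, A)),
        np.zeros((G, A)),
        np.zeros((n, A)),
    )
    ssy, ssx = np.zeros(A), np.zeros(A)
    for a in range(A):
        w, t, c, p_load = _nipals_component(Xd, Yd)
        W[:, a], T[:, a], C[:, a], P[:, a] = w, t, c, p_load
        tt = float(t @ t)
        ssy[a] = tt * float(c @ c)
        ssx[a] = tt * float(p_load @ p_load)
        Xd -= np.outer(t, p_load)
        Yd -= np.outer(t, c)
    return PlsdaModel(
        n_components=A,
        weights=W,
        x_loadings=P,
        y_loadings=C,
        scores=T,
        ssy=ssy,
        ssx=ssx,
        r2x=float(ssx.sum() / ssx_total) if ssx_total > 0 else 0.0,
        r2y=float(ssy.sum() / ssy_total) if ssy_total > 0 else 0.0,
        x_scaler=scaler,
        y_mean=y_mean,
        feature_names=feature_names,
    )


def compute_vip(model: PlsdaModel) -> pd.Series:
    """Variable importance in projection for every predictor.

    ``VIP_j = sqrt(p * sum_a ssy_a w_aj^2 / sum_a ssy_a)``; with unit-norm
    weight vectors the squared VIPs average exactly 1.
    """
    ssy = model.ssy
    if not np.any(ssy > 0):
        raise ValidationError("model explains no Y variance; VIP undefined")
    W = model.weights
    p = W.shape[0]
    vip = np.sqrt(p * (W**2 @ ssy) / ssy.sum())
    names = (
        model.feature_names
        if model.feature_names is not None
        else [f"x{j}" for j in range(p)]
    )
    return pd.Series(vip, index=list(names), name="VIP")


@dataclass
class PermutationReport:
    """SIMCA-style permutation-validation summary.

    ``correlations`` holds the label-correlation statistic per refit (1.0
    for the original model, listed last); ``r2y``/``q2`` are the matching
    model diagnostics.  Intercepts come from least-squares lines through all
    ``n_permutations + 1`` points, evaluated at correlation 0.
    """

    correlations: np.ndarray
    r2y: np.ndarray
    q2: np.ndarray
    r2_intercept: float
    q2_intercept: float
    original_r2y: float
    original_q2: float

    @property
    def n_permutations(self) -> int:
        return len(self.correlations) - 1

    def to_frame(self) -> pd.DataFrame:
        kind = ["permuted"] * self.n_permutations + ["original"]
        return pd.DataFrame(
            {
                "correlation": self.correlations,
                "r2y": self.r2y,
                "q2": self.q2,
                "kind": kind,
            }
        )


def _label_correlation(Y_perm: np.ndarray, Y_orig: np.ndarray) -> float:
    """Mean absolute column-wise Pearson correlation between dummy matrices."""
    cors = []
    for j in range(Y_orig.shape[1]):
        a, b = Y_perm[:, j], Y_orig[:, j]
        if a.std() == 0 or b.std() == 0:
            continue
        cors.append(abs(np.corrcoef(a, b)[0, 1]))
    return float(np.mean(cors)) if cors else 0.0


def permutation_test(
    X: Union[np.ndarray, pd.DataFrame],
    groups: Sequence[str],
    n_components: int,
    n_permutations: int = 200,
    seed: int = 1,
    folds: int = 7,
    group_labels: Optional[Sequence[str]] = None,
) -> PermutationReport:
    """Refit the model on label-permuted data ``n_permutations`` times.

    Group labels are permuted jointly across rows; R2Y and Q2 (same fold
    scheme as the original) are recorded together with the label-correlation
    statistic.  Overfitting shows as permuted diagnostics approaching the
    originals; a valid model keeps all permuted Q2 below the original and
    has a negative Q2 regression intercept.
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    labels = (
        list(group_labels)
        if group_labels is not None
        else list(dict.fromkeys(groups))
    )
    Y = one_hot(list(groups), labels)
    original = fit_plsda_fixed(X, Y, n_components)
    orig_q2 = cross_validated_q2(X, Y, n_components, folds)

    rng = np.random.default_rng(seed)
    cors, r2s, q2s = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # permuted splits may drop a class
        for _ in range(n_permutations):
            perm = rng.permutation(len(groups))
            Y_perm = Y[perm]
            cors.append(_label_correlation(Y_perm, Y))
            sub = fit_plsda_fixed(X, Y_perm, n_components)
            r2s.append(sub.r2y)
            q2s.append(cross_validated_q2(X, Y_perm, n_components, folds))
    cors.append(1.0)
    r2s.append(original.r2y)
    q2s.append(orig_q2)

    cors_arr = np.asarray(cors)
    r2_arr = np.asarray(r2s)
    q2_arr = np.asarray(q2s)
    r2_line = np.polyfit(cors_arr, r2_arr, 1)
    q2_line = np.polyfit(cors_arr, q2_arr, 1)
    return PermutationReport(
        correlations=cors_arr,
        r2y=r2_arr,
        q2=q2_arr,
        r2_intercept=float(r2_line[1]),
        q2_intercept=float(q2_line[1]),
        original_r2y=float(original.r2y),
        original_q2=float(orig_q2),
    )


@dataclass
class HotellingEllipse:
    """Axis-aligned 95% (by default) confidence ellipse in a 2-D score plot."""

    semi_axis_1: float
    semi_axis_2: float
    alpha: float

    def contains(self, scores: np.ndarray) -> np.ndarray:
        """Boolean mask: True for points inside (or on) the ellipse."""
        s = np.atleast_2d(np.asarray(scores, dtype=float))
        r = (s[:, 0] / self.semi_axis_1) ** 2 + (s[:, 1] / self.semi_axis_2) ** 2
        return r <= 1.0

    def outliers(self, scores: np.ndarray) -> np.ndarray:
        return ~self.contains(scores)


def hotelling_ellipse(scores: np.ndarray, alpha: float = 0.05) -> HotellingEllipse:
    """Hotelling's T2 confidence ellipse for a two-column score matrix.

    Semi-axis for component k is
    ``s_k * sqrt(2 (n-1)(n+1) / (n (n-2)) * F_{1-alpha}(2, n-2))`` with
    ``s_k`` the sample SD of the scores, which are centered by construction.
    """
    s = np.asarray(scores, dtype=float)
    if s.ndim != 2 or s.shape[1] < 2:
        raise ValidationError("need an n x 2 score matrix")
    n = s.shape[0]
    if n < 4:
        raise ValidationError("Hotelling ellipse needs at least 4 points")
    fcrit = stats.f.ppf(1.0 - alpha, 2, n - 2)
    factor = np.sqrt(2.0 * (n - 1) * (n + 1) / (n * (n - 2)) * fcrit)
    sd = s[:, :2].std(axis=0, ddof=1)
    return HotellingEllipse(
        semi_axis_1=float(sd[0] * factor),
        semi_axis_2=float(sd[1] * factor),
        alpha=alpha,
    )
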