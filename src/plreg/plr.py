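"""Parametric linear regression (PLR) for linearly related variable vectors.

A set of m variable vectors that lie, up to measurement noise, on a common
straight line in R^m is fitted in parametric form ``u = a + b*t``.  The
parameter t is realized as the convex weighted average
``tau = sum_j w_j y_j`` of the columns; each column is then regressed on tau
with the weighted least-squares normal equations, yielding a slope vector
``b = (b_j)``.  Pairwise Cartesian slopes are component ratios
``b_jk = b_j / b_k`` (homogeneous coordinates: the common kappa_tau^-1
attenuation factor cancels and is reported but never applied).

With the minimum-CVE weights (w_j proportional to the column
signal-to-noise ratio mean_j / Var(e_j)) the pairwise slopes are unbiased
estimates of the generative slope even when every column carries error —
unlike the naive WLS slope, which is attenuated by the reliability ratio of
its regressor.

The module also provides the parametric covariance vector
``(Cov(tau, y_j))_j`` and the parametric correlation ``r_PLR``, the product
of the per-column correlations with tau; both reduce to their classical
bivariate counterparts when tau coincides with one of the columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import (
    ConvexWeights,
    ErrorModelError,
    QuadraticErrorModel,
    WeightedAverageResult,
    error_variances_for,
    min_cve_weights,
    weighted_average_result,
)
from .regression import LineModel, SingularFitError, WRFit, wr_fit

__all__ = [
    "LRVVSet",
    "PLRFit",
    "ParametricCovariance",
    "PLRRegressor",
    "weighted_average_vector",
    "pearson_r",
    "plr_fit",
    "plr_slope_vs_weight",
    "parametric_covariance",
    "parametric_correlation",
]


@dataclass(frozen=True)
class LRVVSet:
    """An n x m matrix of joint observations of m linearly related variable
    vectors, with column names and optional row identifiers."""

    data: np.ndarray
    columns: tuple[str, ...] | None = None
    row_ids: tuple | None = None

    def __post_init__(self) -> None:
        data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not np.all(np.isfinite(data)):
            raise ValueError("LRVV data must be finite")
        cols = self.columns
        if cols is None:
            cols = tuple(f"y{j + 1}" for j in range(data.shape[1]))
        else:
            cols = tuple(cols)
            if len(cols) != data.shape[1]:
                raise ValueError("column-name count does not match data width")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "columns", cols)

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def m(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class PLRFit:
    """Result of a parametric linear regression fit."""

    tau_result: WeightedAverageResult
    component_fits: tuple[WRFit, ...]
    line: LineModel
    pairwise_slope: np.ndarray
    r_vector: np.ndarray
    r_plr: float
    predicted: np.ndarray

    @property
    def intercept(self) -> np.ndarray:
        return self.line.intercept

    @property
    def slope(self) -> np.ndarray:
        return self.line.slope


@dataclass(frozen=True)
class ParametricCovariance:
    """Covariance vector ``(Cov(tau, y_j))_j`` for a given parameter tau.

    Component ratios are the parametric-OLR pairwise slopes; they are
    invariant to the variance divisor (n vs n-1) since it cancels.
    """

    components: np.ndarray
    columns: tuple[str, ...]


def weighted_average_vector(Y: LRVVSet | np.ndarray, w: ConvexWeights) -> np.ndarray:
    """tau_i = sum_j w_j y_ij."""
    data = Y.data if isinstance(Y, LRVVSet) else np.atleast_2d(np.asarray(Y, float))
    if data.shape[1] != len(w):
        raise ValueError(f"{len(w)} weights for {data.shape[1]} columns")
    return data @ w.w


def pearson_r(x, y) -> float:
    """Pearson correlation: cosine of the angle between centered vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


def _as_lrvv(Y) -> LRVVSet:
    return Y if isinstance(Y, LRVVSet) else LRVVSet(np.asarray(Y, dtype=float))


def _resolve_weights(Y: LRVVSet, var_matrix: np.ndarray, weights) -> ConvexWeights:
    if isinstance(weights, ConvexWeights):
        return weights
    if weights is None or (isinstance(weights, str) and weights == "auto"):
        # column Var(e_j) = mean of the per-observation expected variances
        var_means = var_matrix.mean(axis=0)
        if np.max(var_means) < 1e-100:
            # error-free columns: every weighting is equivalent (kappa = 1)
            return ConvexWeights(np.full(Y.m, 1.0 / Y.m))
        return min_cve_weights(Y.data.mean(axis=0), var_means)
    return ConvexWeights(np.asarray(weights, dtype=float))


def _wp_predict_multi(Y: LRVVSet, line: LineModel, var_matrix: np.ndarray) -> np.ndarray:
    """Weighted-average prediction of each observation onto the fitted line.

    Each axis j proposes the parameter value t_j = (g_j - a_j)/b_j at which
    the line reproduces the observed coordinate; the predicted point is the
    line evaluated at the signal-to-noise weighted average of the t_j, with
    per-point weights proportional to mean_j / s2_ij.  Lies on the line by
    construction.
    """
    a, b = line.intercept, line.slope
    t_candidates = (Y.data - a) / b  # n x m
    col_means = Y.data.mean(axis=0)
    raw = col_means / np.maximum(var_matrix, np.finfo(float).tiny)
    w = raw / raw.sum(axis=1, keepdims=True)
    t_hat = np.sum(w * t_candidates, axis=1)
    return line(t_hat)


def plr_fit(Y, error_model, weights="auto") -> PLRFit:
    """Fit the parametric linear regression to a set of LRVVs.

    Parameters
    ----------
    Y : LRVVSet or array of shape (n, m)
        Joint observations; n >= 3.
    error_model : QuadraticErrorModel, sequence thereof, or ExplicitErrorModel
        Evaluated at the observed values to obtain per-point expected
        variances.
    weights : "auto", ConvexWeights, or array
        "auto" uses the minimum-CVE weights built from column means and
        column-mean error variances.
    """
    Y = _as_lrvv(Y)
    if Y.n < 3:
        raise ValueError("PLR requires at least 3 observations")
    var_matrix = error_variances_for(error_model, Y.data)
    var_matrix = np.maximum(var_matrix, np.finfo(float).tiny)
    w = _resolve_weights(Y, var_matrix, weights)
    tau_res = weighted_average_result(Y.data, w, var_matrix.mean(axis=0))
    tau = tau_res.tau
    if np.ptp(tau) == 0:
        raise SingularFitError("weighted average tau is constant")

    fits = tuple(
        wr_fit(tau, Y.data[:, j], var_matrix[:, j]) for j in range(Y.m)
    )
    a = np.array([f.intercept for f in fits])
    b = np.array([f.slope for f in fits])
    line = LineModel(intercept=a, slope=b)
    with np.errstate(divide="ignore", invalid="ignore"):
        pairwise = np.outer(b, 1.0 / b)
    r_vec = np.array([pearson_r(tau, Y.data[:, j]) for j in range(Y.m)])
    r_plr = float(np.prod(r_vec))
    predicted = _wp_predict_multi(Y, line, var_matrix)
    return PLRFit(
        tau_result=tau_res,
        component_fits=fits,
        line=line,
        pairwise_slope=pairwise,
        r_vector=r_vec,
        r_plr=r_plr,
        predicted=predicted,
    )


def plr_slope_vs_weight(Y, error_model, w_grid) -> np.ndarray:
    """Pairwise slope b_21 = b_2/b_1 across a grid of weights w on column 1.

    Only defined for m = 2.  Endpoints w=1 and w=0 equal the direct WLS
    slope and the inverse of the reversed WLS slope respectively; for noisy
    data with positive slope the sequence decreases monotonically in w.
    Returns an array of (w, slope) rows.
    """
    Y = _as_lrvv(Y)
    if Y.m != 2:
        raise ValueError("slope-vs-weight profile is defined for m=2 only")
    out = []
    for w in np.asarray(w_grid, dtype=float):
        fit = plr_fit(Y, error_model, weights=ConvexWeights([w, 1.0 - w]))
        out.append((w, fit.pairwise_slope[1, 0]))
    return np.array(out)


def parametric_covariance(Y, tau) -> ParametricCovariance:
    """Covariance vector ``(Cov(tau, y_j))_j`` (n-1 divisor)."""
    Y = _as_lrvv(Y)
    tau = np.asarray(tau, dtype=float)
    if np.ptp(tau) == 0:
        raise ValueError("parametric covariance undefined for constant tau")
    tau_c = tau - tau.mean()
    comps = (Y.data - Y.data.mean(axis=0)).T @ tau_c / (len(tau) - 1)
    return ParametricCovariance(components=comps, columns=Y.columns)


def parametric_correlation(Y, tau) -> dict:
    """Parametric correlation vector and coefficient.

    ``r_vector[j]`` is the Pearson correlation of column j with tau;
    ``r_PLR`` is their product (the m-fold contraction of the alignment
    polyads reduced to product form).  When tau equals one of two columns,
    r_PLR reduces to the classical Pearson r of the pair.
    """
    Y = _as_lrvv(Y)
    tau = np.asarray(tau, dtype=float)
    r_vec = np.array([pearson_r(tau, Y.data[:, j]) for j in range(Y.m)])
    return {"r_vector": r_vec, "r_plr": float(np.prod(r_vec))}


class PLRRegressor(RegressorMixin, BaseEstimator):
    """Parametric linear regression estimator for multidimensional
    measurement-error data.

    Fits a line in R^m to an (n, m) matrix whose columns are linearly
    related variable vectors, all subject to measurement error described by
    ``error_model``.  The scikit-learn conventions apply: hyperparameters
    are constructor arguments, fitted results carry trailing underscores,
    and ``transform``/``predict`` map observations onto the fitted line.

    Parameters
    ----------
    error_model : QuadraticErrorModel, sequence of them (one per column),
        ExplicitErrorModel, or tuple (q0, q1, q2)
        Expected-variance model, evaluated at the observed values.
    weights : "auto" (default), ConvexWeights, or array-like
        Convex weights defining the parameter tau.  "auto" derives
        minimum-CVE weights from column signal-to-noise ratios.

    Attributes
    ----------
    line_ : LineModel
        Fitted parametric line a + b*t.
    intercept_, slope_ : ndarray of shape (m,)
    pairwise_slope_ : ndarray of shape (m, m)
        Cartesian slopes b_jk = b_j / b_k.
    weights_ : ndarray of shape (m,)
        Convex weights actually used for tau.
    cve_ : float
        Coefficient of variation for error of tau.
    kappa_tau_ : float
        Reliability ratio of tau.
    r_vector_ : ndarray of shape (m,)
    r_plr_ : float
        Parametric correlation coefficient.

    Examples
    --------
    >>> import numpy as np
    >>> from plreg import PLRRegressor, QuadraticErrorModel
    >>> t = np.arange(1.0, 26.0)
    >>> Y = np.column_stack([t, 2.0 * t])
    >>> est = PLRRegressor(error_model=QuadraticErrorModel(0.01, 0, 0))
    >>> est.fit(Y).pairwise_slope_[1, 0]
    2.0
    """

    def __init__(self, error_model=None, weights="auto"):
        self.error_model = error_model
        self.weights = weights

    def _model(self):
        if self.error_model is None:
            raise ErrorModelError(
                "an error model is required for measurement-error regression"
            )
        if isinstance(self.error_model, tuple) and len(self.error_model) == 3 \
                and all(np.isscalar(v) for v in self.error_model):
            return QuadraticErrorModel(*self.error_model)
        return self.error_model

    def fit(self, X, y=None):
        """Fit the parametric line to an (n, m) LRVV matrix X."""
        if not isinstance(X, LRVVSet):
            X = check_array(X, ensure_min_samples=3, ensure_min_features=2)
        fit = plr_fit(X, self._model(), weights=self.weights)
        self.fit_result_ = fit
        self.line_ = fit.line
        self.intercept_ = fit.line.intercept
        self.slope_ = fit.line.slope
        self.pairwise_slope_ = fit.pairwise_slope
        self.weights_ = fit.tau_result.weights.w
        self.cve_ = fit.tau_result.cve
        self.kappa_tau_ = fit.tau_result.kappa_tau
        self.r_vector_ = fit.r_vector
        self.r_plr_ = fit.r_plr
        self.n_features_in_ = fit.line.m
        return self

    def transform(self, X):
        """Project observations onto the fitted line (WP prediction)."""
        check_is_fitted(self, "line_")
        Y = _as_lrvv(check_array(X, ensure_min_samples=1))
        var = error_variances_for(self._model(), Y.data)
        var = np.maximum(var, np.finfo(float).tiny)
        return _wp_predict_multi(Y, self.line_, var)

    def predict(self, X):
        """Alias for :meth:`transform`: predicted points on the MER line."""
        return self.transform(X)
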