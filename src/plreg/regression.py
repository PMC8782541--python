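"""Bivariate measurement-error regression estimators.

Implements the weighted least-squares (WLS) line fit via the normal
equations (solved through a pseudoinverse-style decomposition, never an
explicit inverse), ordinary linear regression, attenuation-corrected slope
estimators and their signal-to-noise-weighted combination, the analytic
weighted orthogonal regression (ORw) closed form, a deterministic numeric
weighted-orthogonal-regression (WOR) minimizer used as an in-repo oracle,
and the weighted-average prediction (WP) mapping of observed points onto a
fitted line.

Notation: for observed vectors (x, y) = (x* + e_x, y* + e_y) with
independent zero-mean normal errors, the naive WLS slope is attenuated by
the reliability ratio kappa_x = 1 - Var(e_x)/Var(x).  The estimators here
correct for that attenuation in different ways.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .errors import min_cve_weights

__all__ = [
    "WRFit",
    "ORWFit",
    "LineModel",
    "wr_fit",
    "olr_slope",
    "attenuation_estimators",
    "orw_fit",
    "wor_numeric",
    "wp_predict",
]


class SingularFitError(ValueError):
    """Raised when a regression design is rank deficient."""


@dataclass(frozen=True)
class WRFit:
    """A weighted least-squares line fit y ~ a + b*t.

    ``predicted = a + b*t`` elementwise; the weighted residuals satisfy the
    normal equations (orthogonality to the design columns under the weight
    metric) to numerical tolerance.
    """

    intercept: float
    slope: float
    predicted: np.ndarray
    residuals: np.ndarray
    weights: np.ndarray


@dataclass(frozen=True)
class ORWFit:
    """Weighted orthogonal regression fit from the analytic closed form.

    ``b_factor`` is the weighted-residual factor B; it is invariant under
    per-axis scaling (x, y) -> (k_x x, k_y y) when the weights are
    recomputed from the scaled data's signal-to-noise ratios.
    """

    slope: float
    intercept: float
    b_factor: float
    w_x: float
    w_y: float


@dataclass(frozen=True)
class LineModel:
    """A line in R^m in parametric form: points are ``a + b * t`` for scalar t."""

    intercept: np.ndarray
    slope: np.ndarray

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.intercept, dtype=float))
        b = np.atleast_1d(np.asarray(self.slope, dtype=float))
        if a.shape != b.shape:
            raise ValueError("intercept and slope must have the same length")
        object.__setattr__(self, "intercept", a)
        object.__setattr__(self, "slope", b)

    @property
    def m(self) -> int:
        return len(self.slope)

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.intercept + np.multiply.outer(t, self.slope)

    def cartesian_slope(self, j: int = 1, k: int = 0) -> float:
        """Pairwise Cartesian slope dy_j/dy_k = b_j / b_k."""
        return float(self.slope[j] / self.slope[k])


def wr_fit(t, y, var_y) -> WRFit:
    """WLS regression of y on t with per-point variances var_y.

    Solves the weighted normal equations ``(X'V^-1 X)^-1 X'V^-1 y`` with
    design ``X = [1, t]`` through a least-squares decomposition of the
    rescaled system (no explicit inverse).  Ordinary linear regression is
    the constant-variance special case.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    var_y = np.broadcast_to(np.asarray(var_y, dtype=float), y.shape).copy()
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("t and y must be 1-D vectors of equal length")
    n = len(t)
    if n < 2:
        raise ValueError("need at least 2 observations")
    if n == 2:
        warnings.warn("n=2: exact interpolation, no residual degrees of freedom",
                      stacklevel=2)
    if np.any(var_y <= 0) or not np.all(np.isfinite(var_y)):
        raise ValueError("variances must be positive and finite")
    if np.ptp(t) == 0:
        raise SingularFitError("design is rank deficient: t is constant")

    # whiten: rows scaled by 1/s so OLS on (X/s, y/s) solves the WLS problem
    s = np.sqrt(var_y)
    X = np.column_stack([np.ones(n), t])
    coef, _, rank, _ = np.linalg.lstsq(X / s[:, None], y / s, rcond=None)
    if rank < 2:
        raise SingularFitError("design is rank deficient")
    a, b = float(coef[0]), float(coef[1])
    predicted = a + b * t
    return WRFit(intercept=a, slope=b, predicted=predicted,
                 residuals=y - predicted, weights=1.0 / var_y)


def olr_slope(x, y) -> float:
    """Ordinary linear regression slope Cov(x, y) / Var(x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx = np.var(x, ddof=1)
    if vx <= 0:
        raise ValueError("OLR slope undefined: x is constant")
    return float(np.cov(x, y, ddof=1)[0, 1] / vx)


def attenuation_estimators(x, y, var_ex: float, var_ey: float) -> dict:
    """Attenuation-corrected slope estimators for errors in both variables.

    Given summarized error variances Var(e_x), Var(e_y) (means of the
    expected per-point variances), computes:

    - ``b_direct``  = b_xy,OLR / kappa_x  (correction for attenuation)
    - ``b_inverse`` = kappa_y / b_yx,OLR  (the reversed-roles estimator)
    - ``b_A``       = arithmetic mean of the two
    - ``b_W``       = signal-to-noise weighted average, with weights
      proportional to (mean(x)/Var(e_x), mean(y)/Var(e_y))

    For any least-squares estimate the direct and inverse OLR slopes bound
    the true-slope estimate: |b_OLR| <= |b| <= |1/b_yx,OLR|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    var_x = np.var(x, ddof=1)
    var_y = np.var(y, ddof=1)
    kappa_x = 1.0 - var_ex / var_x
    kappa_y = 1.0 - var_ey / var_y
    if kappa_x <= 0 or kappa_y <= 0:
        raise ValueError(
            f"error model exceeds data variance (kappa_x={kappa_x:.4g}, "
            f"kappa_y={kappa_y:.4g}); attenuation correction overflows"
        )
    b_xy = olr_slope(x, y)
    b_yx = olr_slope(y, x)
    b_direct = b_xy / kappa_x
    b_inverse = kappa_y / b_yx
    if var_ex == 0 and var_ey == 0:
        # noiseless limit: SNR weights degenerate, both estimators agree
        w = np.array([0.5, 0.5])
    else:
        w = min_cve_weights(
            [x.mean(), y.mean()],
            [max(var_ex, np.finfo(float).tiny), max(var_ey, np.finfo(float).tiny)],
        ).w
    b_w = w[0] * b_direct + w[1] * b_inverse
    return {
        "b_olr": b_xy,
        "b_direct": b_direct,
        "b_inverse": b_inverse,
        "b_A": 0.5 * (b_direct + b_inverse),
        "b_W": float(b_w),
        "kappa_x": float(kappa_x),
        "kappa_y": float(kappa_y),
    }


def _sums_of_squares(x, y):
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ xc), float(yc @ yc), float(xc @ yc)


def orw_fit(x, y, w_x: float, w_y: float) -> ORWFit:
    """Analytic weighted orthogonal regression with per-variable weights.

    The data are notionally rescaled to (w_x x, w_y y), orthogonal
    regression is solved in closed form there, and the slope is transformed
    back, giving ``b = (w_x/w_y) * (-B + sign(S_xy) * sqrt(B^2 + 1))`` with
    the weighted-residual factor
    ``B = [(w_x/w_y) S_xx - (w_y/w_x) S_yy] / (2 S_xy)``.
    Plain orthogonal regression is recovered for w_x = w_y.  The intercept
    passes the line through the centroid.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if w_x <= 0 or w_y <= 0:
        raise ValueError("weights must be positive")
    s_xx, s_yy, s_xy = _sums_of_squares(x, y)
    if s_xy == 0:
        raise ValueError("S_xy = 0: line orientation is ambiguous")
    ratio = w_x / w_y
    B = (ratio * s_xx - s_yy / ratio) / (2.0 * s_xy)
    b = ratio * (-B + np.sign(s_xy) * np.sqrt(B * B + 1.0))
    a = y.mean() - b * x.mean()
    return ORWFit(slope=float(b), intercept=float(a), b_factor=float(B),
                  w_x=float(w_x), w_y=float(w_y))


def wor_numeric(x, y, var_x, var_y, tol: float = 1e-10,
                max_iter: int = 500) -> tuple[float, float]:
    """Numeric weighted orthogonal regression: the in-repo WOR oracle.

    Minimizes ``sum_i [w_yi (a + b x*_i - y_i)^2 + w_xi (x_i - x*_i)^2]``
    over (a, b) with inverse-variance weights, the latent x*_i profiled out
    in closed form:

        x*_i = (w_xi x_i + w_yi b (y_i - a)) / (w_xi + w_yi b^2)

    The outer minimization is a deterministic quasi-Newton search from the
    OLR start point (no randomness), mirroring what ODRPACK computes for a
    straight line.  Returns (a, b).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    var_x = np.broadcast_to(np.asarray(var_x, dtype=float), x.shape)
    var_y = np.broadcast_to(np.asarray(var_y, dtype=float), y.shape)
    if np.any(var_x <= 0) or np.any(var_y <= 0):
        raise ValueError("variances must be positive")
    w_xi = 1.0 / var_x
    w_yi = 1.0 / var_y

    def objective(ab):
        a, b = ab
        x_star = (w_xi * x + w_yi * b * (y - a)) / (w_xi + w_yi * b * b)
        return np.sum(w_yi * (a + b * x_star - y) ** 2
                      + w_xi * (x - x_star) ** 2)

    b0 = olr_slope(x, y)
    a0 = y.mean() - b0 * x.mean()
    res = minimize(objective, x0=np.array([a0, b0]), method="BFGS",
                   options={"gtol": tol, "maxiter": max_iter})
    if not (res.success or res.status == 2):
        # status 2 = precision loss, common at machine-precision optima
        raise RuntimeError(f"WOR minimization did not converge: {res.message}")
    return float(res.x[0]), float(res.x[1])


def wp_predict(point, line, var_point, means) -> np.ndarray:
    """Weighted-average prediction of an observed point onto a line.

    The candidate predictions ``v_x = (x_i, b x_i + a)`` (as if x were
    error-free) and ``v_y = ((y_i - a)/b, y_i)`` (as if y were error-free)
    bound a segment on the line; the returned point is their convex
    combination with weight ``w = (1 + (ybar/xbar)(s2_xi/s2_yi))^-1`` from
    the signal-to-noise ratios.  The result always lies on the line.
    """
    x_i, y_i = float(point[0]), float(point[1])
    a, b = float(line[0]), float(line[1])
    s2_x, s2_y = float(var_point[0]), float(var_point[1])
    xbar, ybar = float(means[0]), float(means[1])
    if b == 0:
        raise ValueError("WP prediction undefined for zero slope")
    if xbar <= 0 or ybar <= 0:
        raise ValueError("WP weighting requires positive means")
    if s2_x < 0 or s2_y < 0:
        raise ValueError("variances must be nonnegative")
    v_x = np.array([x_i, b * x_i + a])
    v_y = np.array([(y_i - a) / b, y_i])
    if s2_y == 0:
        if s2_x == 0:
            if abs(y_i - (a + b * x_i)) > 1e-12 * max(1.0, abs(y_i)):
                raise ValueError(
                    "both variances zero but point is off the line: "
                    "prediction ambiguous"
                )
            return np.array([x_i, y_i])
        w = 0.0
    else:
        w = 1.0 / (1.0 + (ybar / xbar) * (s2_x / s2_y))
    return w * v_x + (1.0 - w) * v_y
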