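"""Error models, reliability ratios, and convex weighting of variable vectors.

Measurement-error regression (MER) requires an explicit error model for the
data: every observed value carries an *expected variance* describing the
stochastic error of the acquisition process.  Two representations are
supported: a quadratic variance law ``s2(v) = q0 + q1*v + q2*v**2`` (the
conical model used for read-count data, where q0 is background noise, q1 the
Poisson-like component and q2 overdispersion) and an explicit per-observation
variance matrix.

The module also implements the convex weighting of a set of linearly related
variable vectors (LRVVs).  The weighted average ``tau = sum_j w_j * y_j``
partially cancels independent error; the weights minimizing the coefficient
of variation for error (CVE) are proportional to the per-column
signal-to-noise ratios ``mean_j / Var(e_j)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QuadraticErrorModel",
    "ExplicitErrorModel",
    "ConvexWeights",
    "WeightedAverageResult",
    "eval_error_model",
    "reliability_ratio",
    "min_cve_weights",
    "cve",
    "deming_weights",
    "weighted_average_error_variance",
]

#: tolerance on |sum(w) - 1| after construction of ConvexWeights
WEIGHT_SUM_TOL = 1e-12


class ErrorModelError(ValueError):
    """Raised when an error model is invalid or evaluates to a negative variance."""


@dataclass(frozen=True)
class QuadraticErrorModel:
    """Quadratic variance law ``s2(v) = q0 + q1*v + q2*v**2``.

    Parameters
    ----------
    q0 : float
        Variance offset (background noise), must be >= 0.
    q1 : float
        Linear (Poisson-like) coefficient, in data units.
    q2 : float
        Dimensionless overdispersion coefficient.
    """

    q0: float
    q1: float
    q2: float

    def __post_init__(self) -> None:
        if self.q0 < 0:
            raise ErrorModelError(f"q0 must be nonnegative, got {self.q0}")

    def __call__(self, values: np.ndarray) -> np.ndarray:
        return eval_error_model(self, values)

    @property
    def q(self) -> tuple[float, float, float]:
        return (self.q0, self.q1, self.q2)


@dataclass(frozen=True)
class ExplicitErrorModel:
    """Explicit per-observation expected error variances.

    ``variances`` is an n x m matrix aligned with the data it describes;
    all entries must be nonnegative.
    """

    variances: np.ndarray

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.variances, dtype=float))
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ErrorModelError("explicit variances must be finite and nonnegative")
        object.__setattr__(self, "variances", v)


def eval_error_model(model: QuadraticErrorModel, values) -> np.ndarray:
    """Evaluate a quadratic error model elementwise.

    Returns ``q0 + q1*v + q2*v**2`` for each value.  A negative evaluated
    variance indicates an invalid model on the data's support and raises
    :class:`ErrorModelError` naming the offending value.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ErrorModelError("values must be finite")
    s2 = model.q0 + model.q1 * v + model.q2 * v**2
    if np.any(s2 < 0):
        bad = v[np.argmin(s2)] if v.ndim else v
        raise ErrorModelError(
            f"error model {model.q} evaluates to a negative variance at value {bad!r}"
        )
    return s2


def error_variances_for(model, data: np.ndarray) -> np.ndarray:
    """Per-observation expected variances for ``data`` (n x m) under ``model``.

    ``model`` may be a single QuadraticErrorModel (shared across columns), a
    sequence of per-column QuadraticErrorModels, or an ExplicitErrorModel.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if isinstance(model, ExplicitErrorModel):
        if model.variances.shape != data.shape:
            raise ErrorModelError(
                f"explicit variance shape {model.variances.shape} does not match "
                f"data shape {data.shape}"
            )
        return model.variances
    if isinstance(model, QuadraticErrorModel):
        return eval_error_model(model, data)
    models = list(model)
    if len(models) != data.shape[1]:
        raise ErrorModelError(
            f"{len(models)} column models for {data.shape[1]} columns"
        )
    return np.column_stack(
        [eval_error_model(m, data[:, j]) for j, m in enumerate(models)]
    )


@dataclass(frozen=True)
class ConvexWeights:
    """m nonnegative weights summing to 1, defining ``tau = sum_j w_j y_j``.

    Weights are renormalized once on construction; negative entries are
    rejected.
    """

    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.atleast_1d(np.asarray(self.w, dtype=float))
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValueError(f"weights must be finite and nonnegative, got {w}")
        total = w.sum()
        if total <= 0:
            raise ValueError("weights must have a positive sum")
        w = w / total
        assert abs(w.sum() - 1.0) <= WEIGHT_SUM_TOL
        object.__setattr__(self, "w", w)

    def __len__(self) -> int:
        return len(self.w)

    def __iter__(self):
        return iter(self.w)


@dataclass(frozen=True)
class WeightedAverageResult:
    """A weighted average tau of LRVVs together with its error summary.

    Attributes
    ----------
    tau : ndarray
        The n-vector ``sum_j w_j y_j``.
    weights : ConvexWeights
    cve : float
        Coefficient of variation for error, ``sqrt(Var(e_tau)) / mean(tau)``.
    kappa_tau : float
        Reliability ratio of tau, ``1 - Var(e_tau)/Var(tau)``, in [0, 1].
    var_e_tau : float
        Propagated error variance ``sum_j w_j**2 Var(e_j)``.
    """

    tau: np.ndarray
    weights: ConvexWeights
    cve: float
    kappa_tau: float
    var_e_tau: float


def _sample_var(x: np.ndarray) -> float:
    # n-1 divisor throughout; slope/ratio quantities are divisor-invariant
    return float(np.var(np.asarray(x, dtype=float), ddof=1))


def reliability_ratio(values, error_variances) -> float:
    """Reliability ratio ``kappa = 1 - Var(e)/Var(values)``, clipped to [0, 1].

    ``Var(e)`` is the mean of the per-observation expected error variances,
    even under heteroscedasticity.  The naive regression slope on a noisy
    regressor is attenuated by exactly this factor; kappa = 1 means the
    vector is effectively error-free.
    """
    x = np.asarray(values, dtype=float)
    s2 = np.broadcast_to(np.asarray(error_variances, dtype=float), x.shape)
    var_x = _sample_var(x)
    if var_x <= 0:
        raise ValueError("reliability ratio undefined for a constant vector")
    var_e = float(np.mean(s2))
    kappa = 1.0 - var_e / var_x
    if kappa < 0:
        warnings.warn(
            f"mean error variance {var_e:.4g} exceeds data variance {var_x:.4g}; "
            "reliability ratio clipped to 0",
            stacklevel=2,
        )
        kappa = 0.0
    return min(kappa, 1.0)


def min_cve_weights(means, error_variances) -> ConvexWeights:
    """Convex weights minimizing the CVE of the weighted average.

    ``w_j`` is proportional to the signal-to-noise ratio
    ``mean_j / Var(e_j)``, normalized to sum to one.  All means and error
    variances must be strictly positive (the weighting assumes positive
    signal).
    """
    mu = np.atleast_1d(np.asarray(means, dtype=float))
    var_e = np.atleast_1d(np.asarray(error_variances, dtype=float))
    if mu.shape != var_e.shape:
        raise ValueError("means and error variances must have the same length")
    if np.any(mu <= 0):
        raise ValueError(f"min-CVE weighting requires positive means, got {mu}")
    if np.any(var_e <= 0):
        raise ValueError(f"min-CVE weighting requires positive variances, got {var_e}")
    return ConvexWeights(mu / var_e)


def deming_weights(error_variances) -> ConvexWeights:
    """Inverse-variance (Deming) weights ``w_j`` proportional to ``1/Var(e_j)``.

    Deming weighting is scale-consistent but does not minimize the CVE of
    the weighted average; it is provided for comparison.
    """
    var_e = np.atleast_1d(np.asarray(error_variances, dtype=float))
    if np.any(var_e <= 0):
        raise ValueError(f"Deming weighting requires positive variances, got {var_e}")
    return ConvexWeights(1.0 / var_e)


def weighted_average_error_variance(weights: ConvexWeights, error_variances) -> float:
    """Propagated error variance of tau: ``sum_j w_j**2 Var(e_j)``.

    Assumes independent errors across columns (all error cross-covariances
    zero).
    """
    var_e = np.atleast_1d(np.asarray(error_variances, dtype=float))
    return float(np.sum(weights.w**2 * var_e))


def cve(weights: ConvexWeights, means, error_variances) -> float:
    """Coefficient of variation for error of the weighted average.

    ``sqrt(sum_j w_j**2 Var(e_j)) / sum_j w_j mean_j``; errors are assumed
    independent across columns.
    """
    mu = np.atleast_1d(np.asarray(means, dtype=float))
    tau_bar = float(np.sum(weights.w * mu))
    if tau_bar == 0:
        raise ZeroDivisionError("CVE undefined: weighted mean of tau is zero")
    return np.sqrt(weighted_average_error_variance(weights, error_variances)) / tau_bar


def weighted_average_result(data, weights: ConvexWeights, column_error_variances) -> WeightedAverageResult:
    """Build tau from an n x m data matrix and summarize its error.

    ``column_error_variances`` are the per-column Var(e_j) summaries (mean
    expected variances).  kappa_tau is computed from the propagated
    Var(e_tau) against the sample variance of tau and clipped to [0, 1].
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    tau = data @ weights.w
    var_e_tau = weighted_average_error_variance(weights, column_error_variances)
    var_tau = _sample_var(tau)
    if var_tau <= 0:
        raise ValueError("degenerate weighted average: tau is constant")
    kappa = float(np.clip(1.0 - var_e_tau / var_tau, 0.0, 1.0))
    tau_bar = float(tau.mean())
    if tau_bar == 0:
        raise ZeroDivisionError("CVE undefined: mean of tau is zero")
    c = float(np.sqrt(var_e_tau) / tau_bar)
    return WeightedAverageResult(
        tau=tau, weights=weights, cve=c, kappa_tau=kappa, var_e_tau=var_e_tau
    )
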