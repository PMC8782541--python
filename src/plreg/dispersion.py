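"""Iterative conical-dispersion error-model pipeline for replicated counts.

Replicated RNA-Seq read counts for the same library are linearly related
variable vectors: each tag's m replicate counts scatter about a line in
replicate space.  After normalizing that line to the unit diagonal, the
scatter of an observation vector g about its replicate mean gbar grows with
gbar — a "conical" dispersion modeled by the quadratic law

    MSD(gbar) = q0 + q1*gbar + q2*gbar**2

where q0 is background noise, q1 the Poisson-like component, and q2 the
overdispersion that dominates at high counts and indexes data quality.

The pipeline alternates: fit the multidimensional MER line by parametric
linear regression with minimum-CVE weights -> normalize the counts onto the
unit line -> decompose each tag into (mean, deviation) and compute the mean
squared deviation (MSD, divisor m) -> weighted quadratic regression of MSD
on gbar -> update the error model; iterating until the coefficients
stabilize.  The fitted law then scales per-tag deviations into
``delta_rms = sqrt(MSD / s2(gbar))``; for purely normal replicate noise
``m * delta_rms**2`` follows a chi-squared law with m-1 degrees of freedom,
so the empirical survival curve of delta_rms against that reference exposes
heavy-tailed (irreproducible) tags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .errors import QuadraticErrorModel, eval_error_model
from .plr import LRVVSet, plr_fit
from .regression import LineModel

__all__ = [
    "CountMatrix",
    "DispersionFit",
    "SurvivalCurve",
    "ConicalDispersion",
    "min_count_set",
    "initial_error_guess",
    "fit_mer_line",
    "normalize_to_unit_line",
    "decompose",
    "msd",
    "fit_quadratic_msd",
    "run_dispersion_pipeline",
    "scaled_difference",
    "threshold_curve",
    "scaled_rms_deviation",
    "survival_function",
    "chisq_reference",
]

# typical windows for the conical coefficients on real count data
Q0_WINDOW = (1.0, 50.0)
Q2_WINDOW = (0.002, 0.05)


@dataclass(frozen=True)
class CountMatrix:
    """Nonnegative replicate count matrix with unique tag identifiers."""

    counts: np.ndarray
    tag_ids: tuple = None

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.counts, dtype=float))
        if c.shape[1] < 2:
            raise ValueError("at least 2 replicates are required")
        if np.any(c < 0) or not np.all(np.isfinite(c)):
            raise ValueError("counts must be finite and nonnegative")
        ids = self.tag_ids
        if ids is None:
            ids = tuple(range(c.shape[0]))
        else:
            ids = tuple(ids)
            if len(ids) != c.shape[0]:
                raise ValueError("tag-ID count does not match row count")
            if len(set(ids)) != len(ids):
                raise ValueError("tag IDs must be unique")
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "tag_ids", ids)

    @property
    def n_tags(self) -> int:
        return self.counts.shape[0]

    @property
    def m_reps(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class SurvivalCurve:
    """Empirical survival function S(v) = P(value > v) at sorted values."""

    values: np.ndarray
    survival: np.ndarray

    def __call__(self, v) -> np.ndarray:
        # step function: S(v) = survival at the largest tabulated value <= v
        idx = np.searchsorted(self.values, np.asarray(v, dtype=float),
                              side="right")
        return np.where(idx == 0, 1.0, self.survival[np.maximum(idx - 1, 0)])


@dataclass(frozen=True)
class DispersionFit:
    """Fitted conical error model and per-tag dispersion summaries.

    ``mask_*`` arrays are over all tags; excluded-from-fit tags remain in
    the per-tag outputs (all data stay in reports, only the regression
    drops them).
    """

    q: tuple
    gbar: np.ndarray
    msd: np.ndarray
    delta_rms: np.ndarray
    mask_zero_mean: np.ndarray
    mask_high_mean: np.ndarray
    mask_outlier: np.ndarray
    line: LineModel
    normalized: np.ndarray
    trace: tuple
    converged: bool
    excluded_fraction: float

    @property
    def error_model(self) -> QuadraticErrorModel:
        return QuadraticErrorModel(*self.q)


def min_count_set(counts: CountMatrix, fraction: float = 0.01) -> np.ndarray:
    """Indices of the lowest-mean `fraction` of tags, excluding zero means.

    Ties at the cutoff are broken by tag order, so the set is deterministic.
    """
    gbar = counts.counts.mean(axis=1)
    nonzero = np.flatnonzero(gbar > 0)
    if nonzero.size == 0:
        raise ValueError("all tags have zero mean count")
    k = max(1, int(round(fraction * nonzero.size)))
    order = nonzero[np.argsort(gbar[nonzero], kind="stable")]
    return np.sort(order[:k])


def initial_error_guess(counts: CountMatrix, q2_init: float = 0.01,
                        fraction: float = 0.01) -> QuadraticErrorModel:
    """Initial conical model s2 = q0 + q2*y**2 from the lowest-count tags.

    q0 is the pooled variance of the minimum-count set (n-1 divisor),
    clamped into the typical window [1, 50] with a warning; q1 starts at 0.
    """
    if not Q2_WINDOW[0] <= q2_init <= Q2_WINDOW[1]:
        warnings.warn(
            f"q2_init={q2_init} outside the typical window {Q2_WINDOW}",
            stacklevel=2,
        )
    idx = min_count_set(counts, fraction)
    pooled = counts.counts[idx].ravel()
    q0 = float(np.var(pooled, ddof=1)) if pooled.size > 1 else 0.0
    if not Q0_WINDOW[0] <= q0 <= Q0_WINDOW[1]:
        clamped = float(np.clip(q0, *Q0_WINDOW))
        warnings.warn(
            f"initial q0={q0:.4g} outside the typical window {Q0_WINDOW}; "
            f"clamped to {clamped}",
            stacklevel=2,
        )
        q0 = clamped
    return QuadraticErrorModel(q0, 0.0, q2_init)


def fit_mer_line(counts: CountMatrix, error_model,
                 fraction: float = 0.01, fit_mask=None) -> LineModel:
    """Fit the MER line through the replicate cloud by PLR.

    The intercept is anchored at the per-replicate mean of the
    minimum-count set (points near the origin); the slope vector comes from
    a PLR fit of the origin-shifted counts with minimum-CVE auto weights.
    """
    idx = min_count_set(counts, fraction)
    a_min = counts.counts[idx].mean(axis=0)
    shifted = counts.counts - a_min
    if fit_mask is not None:
        shifted = shifted[fit_mask]
    if shifted.shape[0] < 3:
        raise ValueError("need at least 3 retained tags to fit the MER line")
    # PLR auto weights need positive column means; shifted columns keep the
    # full dynamic range so their means are safely positive for count data
    fit = plr_fit(LRVVSet(shifted), error_model, weights="auto")
    return LineModel(intercept=a_min, slope=fit.line.slope)


def normalize_to_unit_line(counts: CountMatrix, line: LineModel) -> CountMatrix:
    """Affinely map counts so the MER line becomes the unit diagonal.

    y'_ij = (y_ij - a_j) / b_j.  Negative transformed values (low counts
    below the background intercept) are legitimate and retained, so the
    result is a plain array wrapped without the nonnegativity constraint.
    """
    if np.any(line.slope == 0):
        raise ValueError("cannot normalize: zero slope component")
    out = (counts.counts - line.intercept) / line.slope
    obj = object.__new__(CountMatrix)
    object.__setattr__(obj, "counts", np.atleast_2d(out))
    object.__setattr__(obj, "tag_ids", counts.tag_ids)
    return obj


def decompose(observation) -> tuple[np.ndarray, float]:
    """Split an m-vector into (deviation, mean): g = delta + gbar*1.

    delta sums to zero exactly (orthogonal to the one-vector).
    """
    g = np.asarray(observation, dtype=float)
    gbar = float(g.mean())
    return g - gbar, gbar


def msd(delta) -> float:
    """Mean squared deviation delta.delta / m (divisor m, not m-1)."""
    d = np.asarray(delta, dtype=float)
    return float(d @ d / d.size)


def _decompose_all(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gbar = counts.mean(axis=1)
    delta = counts - gbar[:, None]
    return gbar, np.sum(delta * delta, axis=1) / counts.shape[1]


def fit_quadratic_msd(gbar, msd_values, current_model: QuadraticErrorModel
                      ) -> tuple[float, float, float]:
    """Weighted quadratic regression of per-tag MSD on the tag mean.

    Weights are 1/s^4 with s^2 from the current error model: the MSD of m
    normal replicates is a scaled chi-squared variable whose variance grows
    as s^4, so inverse-fourth-power weighting equalizes the residual scale
    across the count range.  Negative fitted q0 or q2 are clipped to zero
    and the remaining terms refit.
    """
    gbar = np.asarray(gbar, dtype=float)
    msd_values = np.asarray(msd_values, dtype=float)
    if gbar.size < 3 or np.ptp(gbar) == 0:
        raise ValueError("quadratic MSD fit needs >= 3 distinct mean values")
    if gbar.size < 10 or np.ptp(np.log10(np.maximum(gbar, 1e-12))) < 1:
        warnings.warn("fewer than 10 tags or < 1 decade of means: "
                      "quadratic fit may be unstable", stacklevel=2)
    s2 = np.maximum(eval_error_model(current_model, gbar), 1e-12)
    sw = 1.0 / (s2 * s2)  # variance of the MSD scales as s^4

    def _wls(cols):
        X = np.column_stack(cols)
        rw = np.sqrt(sw)
        coef, _, rank, _ = np.linalg.lstsq(X * rw[:, None], msd_values * rw,
                                           rcond=None)
        if rank < X.shape[1]:
            raise ValueError("rank-deficient quadratic MSD design")
        return coef

    ones = np.ones_like(gbar)
    c0, c1, c2 = _wls([ones, gbar, gbar**2])
    if c0 < 0 or c2 < 0:
        # clip negatives to zero and refit the remaining terms
        if c0 < 0 and c2 < 0:
            (c1,) = _wls([gbar])
            c0 = c2 = 0.0
        elif c2 < 0:
            c0, c1 = _wls([ones, gbar])
            c0, c2 = max(c0, 0.0), 0.0
        else:
            c1, c2 = _wls([gbar, gbar**2])
            c0, c2 = 0.0, max(c2, 0.0)
    # zero out numerical noise so a fitted model never oscillates in sign
    scale = max(float(np.max(np.abs(msd_values))), 1.0)
    c0, c1, c2 = (0.0 if abs(c) < 1e-10 * scale else float(c)
                  for c in (c0, c1, c2))
    if c1 < 0 and np.any(c0 + c1 * gbar + c2 * gbar**2 < 0):
        # a negative linear term must not drive the variance law negative
        # on the data's support; drop it and refit the bowl
        c0, c2 = _wls([ones, gbar**2])
        c0, c1, c2 = max(float(c0), 0.0), 0.0, max(float(c2), 0.0)
    return float(c0), float(c1), float(c2)


def scaled_rms_deviation(msd_values, gbar, q) -> np.ndarray:
    """delta_rms = sqrt(MSD / s2(gbar)) with s2 = q0 + q1*g + q2*g^2."""
    model = QuadraticErrorModel(*q)
    s2 = eval_error_model(model, np.asarray(gbar, dtype=float))
    if np.any(s2 <= 0):
        raise ValueError("error model gives nonpositive variance at some gbar")
    return np.sqrt(np.asarray(msd_values, dtype=float) / s2)


def run_dispersion_pipeline(
    counts: CountMatrix,
    q2_init: float = 0.01,
    min_fraction: float = 0.01,
    gmax: float = 2000.0,
    outlier_threshold: float = 6.0,
    tol: float = 1e-3,
    max_iter: int = 20,
) -> DispersionFit:
    """Iterate line fitting and quadratic MSD regression to convergence.

    Tags with zero mean are excluded from fitting; tags with mean above
    ``gmax`` are excluded from fitting (heavy-tail protection) but kept in
    every output; tags whose scaled deviation exceeds ``outlier_threshold``
    after the first pass are flagged and dropped from subsequent quadratic
    refits only.  Convergence: max relative change of (q0, q1, q2) below
    ``tol``.
    """
    raw_gbar = counts.counts.mean(axis=1)
    mask_zero = raw_gbar == 0
    mask_high = raw_gbar > gmax
    fit_mask = ~(mask_zero | mask_high)
    if fit_mask.sum() < 10:
        raise ValueError("too few tags retained for dispersion fitting")
    excluded_fraction = float(mask_high.sum() / counts.n_tags)

    model = initial_error_guess(counts, q2_init=q2_init, fraction=min_fraction)
    q = np.array(model.q)
    trace = [tuple(q)]
    mask_outlier = np.zeros(counts.n_tags, dtype=bool)
    converged = False
    line = None
    norm = None
    gbar = raw_gbar
    msd_all = None

    for _ in range(max_iter):
        line = fit_mer_line(counts, QuadraticErrorModel(*q),
                            fraction=min_fraction, fit_mask=fit_mask)
        norm = normalize_to_unit_line(counts, line)
        gbar, msd_all = _decompose_all(norm.counts)
        keep = fit_mask & ~mask_outlier & (gbar > 0)
        q_new = np.array(
            fit_quadratic_msd(gbar[keep], msd_all[keep], QuadraticErrorModel(*q))
        )
        # flag irreproducible tags for subsequent refits (never from outputs)
        with np.errstate(divide="ignore", invalid="ignore"):
            s2 = np.maximum(q_new[0] + q_new[1] * gbar + q_new[2] * gbar**2,
                            1e-12)
            drms = np.sqrt(msd_all / s2)
        mask_outlier = fit_mask & (drms > outlier_threshold)
        denom = np.maximum(np.abs(q), 1e-12)
        rel_change = np.max(np.abs(q_new - q) / denom)
        q = q_new
        trace.append(tuple(q))
        if rel_change < tol:
            converged = True
            break

    s2 = np.maximum(q[0] + q[1] * gbar + q[2] * gbar**2, 1e-12)
    delta_rms = np.sqrt(msd_all / s2)
    return DispersionFit(
        q=tuple(float(v) for v in q),
        gbar=gbar,
        msd=msd_all,
        delta_rms=delta_rms,
        mask_zero_mean=mask_zero,
        mask_high_mean=mask_high,
        mask_outlier=mask_outlier,
        line=line,
        normalized=norm.counts,
        trace=tuple(trace),
        converged=converged,
        excluded_fraction=excluded_fraction,
    )


def scaled_difference(x: float, y: float, s2x: float, s2y: float) -> float:
    """d = (x - y) / sqrt(s2x + s2y): the difference in error-SD units."""
    denom = s2x + s2y
    if denom <= 0:
        raise ZeroDivisionError("zero combined variance in scaled difference")
    return float((x - y) / np.sqrt(denom))


def threshold_curve(q, d_level: float, x_grid, error_model_x) -> list:
    """Roots y of |scaled_difference(x, y)| = d_level along an x grid.

    For each x, with s2_y = q0 + q1*y + q2*y**2 and s2_x from
    ``error_model_x``, the condition (x - y)^2 = d^2 (s2_x + s2_y) is the
    quadratic

        (q2 - 1/d^2) y^2 + (q1 + 2x/d^2) y + q0 + s2_x - x^2/d^2 = 0

    Returns a list of (x, roots) pairs where roots is the tuple of real
    roots (0, 1 or 2 of them).  The q2 = 1/d^2 degeneracy reduces to a
    linear equation and is handled explicitly.
    """
    q0, q1, q2 = q
    if d_level == 0:
        raise ValueError("d_level must be nonzero")
    inv_d2 = 1.0 / (d_level * d_level)
    out = []
    for x in np.atleast_1d(np.asarray(x_grid, dtype=float)):
        s2x = float(eval_error_model(error_model_x, [x])[0]) \
            if isinstance(error_model_x, QuadraticErrorModel) \
            else float(error_model_x(x))
        A = q2 - inv_d2
        B = q1 + 2.0 * x * inv_d2
        C = q0 + s2x - x * x * inv_d2
        if A == 0:
            roots = (-C / B,) if B != 0 else ()
        else:
            disc = B * B - 4.0 * A * C
            if disc < 0:
                roots = ()
            elif disc == 0:
                roots = (-B / (2.0 * A),)
            else:
                sq = np.sqrt(disc)
                roots = tuple(sorted(((-B - sq) / (2 * A), (-B + sq) / (2 * A))))
        out.append((float(x), roots))
    return out


def survival_function(values) -> SurvivalCurve:
    """Empirical survival curve S(v) = fraction of values strictly > v."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty sample")
    uniq = np.unique(v)
    surv = 1.0 - np.searchsorted(v, uniq, side="right") / v.size
    return SurvivalCurve(values=uniq, survival=surv)


def chisq_reference(m: int, n_tags: int, gbar_values, q, seed: int = 0
                    ) -> tuple[SurvivalCurve, np.ndarray]:
    """Survival curve of delta_rms for purely normal replicate noise.

    Simulates n_tags observation vectors with m replicates each drawn
    N(gbar, s(gbar)) under the true conical model q, and pushes them
    through decompose -> MSD -> scaled deviation.  The statistic
    ``m * delta_rms**2`` follows a chi-squared law with m - 1 degrees of
    freedom (the sample-mean centering removes one degree), which the
    survival curve of real data is compared against.

    Returns (curve, delta_rms values).
    """
    if m < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(seed)
    model = QuadraticErrorModel(*q)
    gbar = np.resize(np.asarray(gbar_values, dtype=float), n_tags)
    s = np.sqrt(eval_error_model(model, gbar))
    sims = gbar[:, None] + rng.standard_normal((n_tags, m)) * s[:, None]
    _, msd_vals = _decompose_all(sims)
    # the deviations are scaled by the TRUE per-tag variance
    drms = np.sqrt(msd_vals / (s * s))
    return survival_function(drms), drms


class ConicalDispersion(BaseEstimator):
    """Scikit-learn-style wrapper around the dispersion pipeline.

    Parameters mirror :func:`run_dispersion_pipeline`; ``fit`` accepts an
    (n_tags, m_reps) count array or a :class:`CountMatrix` and exposes the
    fitted quadratic coefficients as ``q0_``, ``q1_``, ``q2_`` plus per-tag
    diagnostics.

    Examples
    --------
    >>> from plreg import ConicalDispersion
    >>> from plreg.synthdata import CountGeneratorSpec, generate_counts
    >>> cm, truth = generate_counts(CountGeneratorSpec(
    ...     n_tags=3000, m_reps=4, q_true=(10.0, 1.0, 0.01), seed=7))
    >>> est = ConicalDispersion().fit(cm)
    >>> 0.005 < est.q2_ < 0.02
    True
    """

    def __init__(self, q2_init: float = 0.01, min_fraction: float = 0.01,
                 gmax: float = 2000.0, outlier_threshold: float = 6.0,
                 tol: float = 1e-3, max_iter: int = 20):
        self.q2_init = q2_init
        self.min_fraction = min_fraction
        self.gmax = gmax
        self.outlier_threshold = outlier_threshold
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        cm = X if isinstance(X, CountMatrix) else CountMatrix(np.asarray(X))
        res = run_dispersion_pipeline(
            cm,
            q2_init=self.q2_init,
            min_fraction=self.min_fraction,
            gmax=self.gmax,
            outlier_threshold=self.outlier_threshold,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        self.fit_result_ = res
        self.q0_, self.q1_, self.q2_ = res.q
        self.line_ = res.line
        self.converged_ = res.converged
        self.n_iter_ = len(res.trace) - 1
        self.gbar_ = res.gbar
        self.msd_ = res.msd
        self.delta_rms_ = res.delta_rms
        self.excluded_fraction_ = res.excluded_fraction
        return self

    def transform(self, X):
        """Normalize counts onto the fitted unit line."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "line_")
        cm = X if isinstance(X, CountMatrix) else CountMatrix(np.asarray(X))
        return normalize_to_unit_line(cm, self.line_).counts
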