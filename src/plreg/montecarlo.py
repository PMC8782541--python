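"""Monte Carlo simulation of LRVV datasets and estimator distributions.

Measurement-error regression statistics (slopes, correlations) are ratios
of noisy quantities and have skewed sampling distributions without tractable
closed forms; their distributions and confidence intervals are estimated by
simulation.  Datasets are generated as ``y_ij = a_j + b_j t_i + e_ij`` with
independent normal errors whose standard deviations come from the error
model evaluated at the TRUE values (the estimation step evaluates models at
the observed values — that mismatch is the realistic regime).

Confidence intervals are "2-sigma equivalent" percentiles (2.275 / 97.725)
of the empirical distribution, reported as separate +/- deviations from the
median because the distributions are generally skewed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import eval_error_model
from .plr import LRVVSet
from .regression import LineModel

__all__ = [
    "SimulationSpec",
    "MCSummary",
    "simulate_lrvv",
    "mc_estimate",
    "mc_joint_histogram",
]

#: percentiles bracketing +/- 2 standard deviations of a normal law
LOWER_PCT = 100.0 * 0.022750131948179195
UPPER_PCT = 100.0 - LOWER_PCT


@dataclass(frozen=True)
class SimulationSpec:
    """Specification of a Monte Carlo LRVV ensemble.

    Attributes
    ----------
    line : LineModel
        True line; column j of a dataset is a_j + b_j * t + noise.
    t : ndarray
        Design points (the true parameter values). Default 1..25, a
        positive support as required by signal-to-noise weighting.
    error_models : sequence of QuadraticErrorModel
        Per-column variance laws, evaluated at the TRUE column values.
    n_datasets : int
    seed : int
        Root seed; dataset k uses the child stream spawn_key=(k,), so each
        dataset is reproducible independently of batching.
    """

    line: LineModel
    error_models: tuple
    t: np.ndarray = field(default_factory=lambda: np.arange(1.0, 26.0))
    n_datasets: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "error_models", tuple(self.error_models))
        if len(self.error_models) != self.line.m:
            raise ValueError("one error model per line component is required")

    @property
    def true_values(self) -> np.ndarray:
        return self.line(self.t)

    def true_sd(self) -> np.ndarray:
        truth = self.true_values
        return np.column_stack([
            np.sqrt(eval_error_model(m, truth[:, j]))
            for j, m in enumerate(self.error_models)
        ])


def _rng_for(spec: SimulationSpec, dataset_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(dataset_index,))
    )


def simulate_lrvv(spec: SimulationSpec, dataset_index: int = 0) -> LRVVSet:
    """Draw one dataset: truth plus independent normal noise per cell."""
    if not 0 <= dataset_index < spec.n_datasets:
        raise IndexError(f"dataset index {dataset_index} out of range")
    rng = _rng_for(spec, dataset_index)
    truth = spec.true_values
    data = truth + rng.standard_normal(truth.shape) * spec.true_sd()
    return LRVVSet(data)


@dataclass(frozen=True)
class MCSummary:
    """Distribution summary of an estimator over a Monte Carlo ensemble.

    ``lower_dev``/``upper_dev`` are the (positive) distances from the median
    to the 2.275th and 97.725th percentiles — reported separately because
    estimator distributions are generally skewed.
    """

    median: float
    lower_dev: float
    upper_dev: float
    bin_edges: np.ndarray
    counts: np.ndarray
    n_datasets: int
    values: np.ndarray
    n_failures: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


def _evaluate(spec: SimulationSpec, estimator) -> tuple[np.ndarray, int]:
    values, failures = [], 0
    for k in range(spec.n_datasets):
        try:
            values.append(float(estimator(simulate_lrvv(spec, k))))
        except Exception:
            failures += 1
    if failures > 0.01 * spec.n_datasets:
        raise RuntimeError(
            f"estimator failed on {failures}/{spec.n_datasets} datasets"
        )
    return np.asarray(values), failures


def _summarize(values: np.ndarray, n_datasets: int, failures: int,
               bins: int = 100) -> MCSummary:
    med = float(np.median(values))
    lo = float(np.percentile(values, LOWER_PCT))
    hi = float(np.percentile(values, UPPER_PCT))
    counts, edges = np.histogram(values, bins=bins)
    return MCSummary(median=med, lower_dev=med - lo, upper_dev=hi - med,
                     bin_edges=edges, counts=counts, n_datasets=n_datasets,
                     values=values, n_failures=failures)


def mc_estimate(spec: SimulationSpec, estimator, bins: int = 100) -> MCSummary:
    """Distribution of ``estimator(dataset)`` over the ensemble.

    ``estimator`` maps an LRVVSet to a scalar.  Datasets on which it raises
    are counted as failures; more than 1% failures aborts.
    """
    values, failures = _evaluate(spec, estimator)
    return _summarize(values, spec.n_datasets, failures, bins=bins)


def mc_joint_histogram(spec: SimulationSpec, estimator_pair, bins: int = 50):
    """Joint 2-D histogram of two estimators, plus marginal summaries.

    Returns ``(H, xedges, yedges, summary_a, summary_b)`` where the
    marginals of H recover the individual histograms.
    """
    est_a, est_b = estimator_pair
    va, fa = _evaluate(spec, lambda d: (est_a(d)))
    vb, fb = _evaluate(spec, lambda d: (est_b(d)))
    H, xedges, yedges = np.histogram2d(va, vb, bins=bins)
    return (
        H,
        xedges,
        yedges,
        _summarize(va, spec.n_datasets, fa),
        _summarize(vb, spec.n_datasets, fb),
    )
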