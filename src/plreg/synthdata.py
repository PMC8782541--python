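"""Synthetic LRVV datasets and RNA-Seq-like replicate count matrices.

The count generator emulates the statistical regime of replicated bulk
RNA-Seq read counts: true tag abundances spread log-uniformly over several
decades (four by default), replicate values dispersed conically about an
embedded straight line with variance ``q0 + q1*g + q2*g**2`` evaluated at
the true abundance, and a small heavy-tailed subpopulation whose variance
is inflated by a fixed factor, standing in for irreproducible tags caused
by uncontrolled experimental effects.  Counts are floored at zero, which
slightly truncates the noise at the lowest abundances.

Every draw returns a truth record sufficient to score parameter recovery
without re-deriving ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dispersion import CountMatrix
from .errors import QuadraticErrorModel
from .montecarlo import SimulationSpec, simulate_lrvv
from .plr import LRVVSet
from .regression import LineModel

__all__ = ["CountGeneratorSpec", "generate_counts", "generate_lrvv",
           "fig_presets"]


@dataclass(frozen=True)
class CountGeneratorSpec:
    """Controls for the replicate-count generator.

    Attributes
    ----------
    n_tags, m_reps : int
        Matrix shape; m_reps >= 2.
    log10_range : (float, float)
        Range of log10 true abundance; default (0, 4), i.e. counts over
        four decades.
    q_true : (q0, q1, q2)
        Conical variance law evaluated at the true abundance.
    heavy_tail_fraction : float
        Fraction of tags whose noise variance is inflated.
    heavy_tail_inflation : float
        Variance multiplication factor for that subpopulation.
    offsets, scales : per-replicate line parameters
        Replicate j observes ``offset_j + scale_j * g_true + noise``,
        embedding a known MER line (identity by default).
    seed : int
    """

    n_tags: int = 5000
    m_reps: int = 4
    log10_range: tuple = (0.0, 4.0)
    q_true: tuple = (10.0, 1.0, 0.01)
    heavy_tail_fraction: float = 0.0
    heavy_tail_inflation: float = 10.0
    offsets: tuple = None
    scales: tuple = None
    seed: int = 0

    def line(self) -> LineModel:
        a = np.zeros(self.m_reps) if self.offsets is None \
            else np.asarray(self.offsets, dtype=float)
        b = np.ones(self.m_reps) if self.scales is None \
            else np.asarray(self.scales, dtype=float)
        return LineModel(intercept=a, slope=b)


def generate_counts(spec: CountGeneratorSpec) -> tuple[CountMatrix, dict]:
    """Draw a replicate count matrix with known conical dispersion.

    Returns ``(counts, truth)`` where truth records the true abundances,
    the embedded line, the variance law, and the heavy-tail mask.
    """
    if not 0.0 <= spec.heavy_tail_fraction <= 1.0:
        raise ValueError("heavy_tail_fraction must be in [0, 1]")
    model = QuadraticErrorModel(*spec.q_true)
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.log10_range
    g_true = 10.0 ** rng.uniform(lo, hi, size=spec.n_tags)
    line = spec.line()
    base_var = model(g_true)
    heavy = rng.random(spec.n_tags) < spec.heavy_tail_fraction
    var = np.where(heavy, base_var * spec.heavy_tail_inflation, base_var)
    noise = rng.standard_normal((spec.n_tags, spec.m_reps)) * np.sqrt(var)[:, None]
    counts = line.intercept + line.slope * g_true[:, None] + noise
    counts = np.maximum(counts, 0.0)
    truth = {
        "g_true": g_true,
        "line": line,
        "q_true": tuple(spec.q_true),
        "heavy_tail_mask": heavy,
    }
    return CountMatrix(counts), truth


def generate_lrvv(line: LineModel, t_points, error_models, seed: int = 0,
                  dataset_index: int = 0) -> LRVVSet:
    """Draw one LRVV dataset about a known line (shared with montecarlo).

    Thin wrapper over :func:`plreg.montecarlo.simulate_lrvv` so that tests
    and fixtures share a single generative contract.
    """
    spec = SimulationSpec(line=line, error_models=tuple(error_models),
                          t=np.asarray(t_points, dtype=float),
                          n_datasets=max(1, dataset_index + 1), seed=seed)
    return simulate_lrvv(spec, dataset_index)


def fig_presets(name: str, alpha: float) -> tuple[LineModel, tuple]:
    """Simulation presets used throughout the bivariate demonstrations.

    - "homoscedastic": y* = x*, s_y = 0.3, s_x = alpha (constants).
    - "heteroscedastic": y* = x*, s_y = 0.01 + 0.3 y*, s_x = 0.01 + alpha x*.
    - "proportional": y* = 2 x*, s_y = 0.3 y*, s_x = alpha x*.
    - "ratio02": y* = x*, s_y = 0.2 y*, s_x = alpha x*.

    Variance laws are expressed as quadratic models in the true value; note
    s = c0 + c1*v implies s^2 = c0^2 + 2 c0 c1 v + c1^2 v^2.
    """

    def sd_affine(c0: float, c1: float) -> QuadraticErrorModel:
        return QuadraticErrorModel(c0 * c0, 2.0 * c0 * c1, c1 * c1)

    if name == "homoscedastic":
        line = LineModel(intercept=[0.0, 0.0], slope=[1.0, 1.0])
        return line, (sd_affine(alpha, 0.0), sd_affine(0.3, 0.0))
    if name == "heteroscedastic":
        line = LineModel(intercept=[0.0, 0.0], slope=[1.0, 1.0])
        return line, (sd_affine(0.01, alpha), sd_affine(0.01, 0.3))
    if name == "proportional":
        line = LineModel(intercept=[0.0, 0.0], slope=[1.0, 2.0])
        return line, (sd_affine(0.0, alpha), sd_affine(0.0, 0.3))
    if name == "ratio02":
        line = LineModel(intercept=[0.0, 0.0], slope=[1.0, 1.0])
        return line, (sd_affine(0.0, alpha), sd_affine(0.0, 0.2))
    raise ValueError(f"unknown preset {name!r}")
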