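import numpy as np
import pytest

from plreg import LineModel, QuadraticErrorModel, SimulationSpec
from plreg.synthdata import fig_presets


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def noisy_pair(rng):
    """A single bivariate draw about y = 2x with known constant variances."""
    t = np.arange(1.0, 26.0)
    var_x, var_y = 0.25, 0.64
    x = t + rng.normal(0, np.sqrt(var_x), t.size)
    y = 2 * t + rng.normal(0, np.sqrt(var_y), t.size)
    return x, y, var_x, var_y


def make_spec(preset: str, alpha: float, n_datasets: int, seed: int,
              t=None) -> SimulationSpec:
    line, models = fig_presets(preset, alpha)
    kwargs = {} if t is None else {"t": np.asarray(t, dtype=float)}
    return SimulationSpec(line=line, error_models=models,
                          n_datasets=n_datasets, seed=seed, **kwargs)


#: 25 evenly spaced design points on (0, 1]: a regime where constant noise
#: of SD ~0.3 makes the reliability ratio depart visibly from 1
UNIT_DESIGN = np.arange(1.0, 26.0) / 25.0

#: milder design (kappa ~ 0.86 at noise SD 0.3): attenuation is clearly
#: visible but the per-dataset attenuation correction never overflows
MID_DESIGN = np.arange(1.0, 26.0) / 10.0


@pytest.fixture
def exact_line_set():
    """Noiseless LRVVs exactly on y2 = 2*y1 over t = 1..25."""
    t = np.arange(1.0, 26.0)
    return np.column_stack([t, 2.0 * t])
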