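"""Table and config I/O plus JSON/TSV result writers.

Input tables are TSV or CSV with a header row.  The ``lrvv`` schema is a
plain numeric matrix (one column per variable vector); the ``counts``
schema additionally requires a leading tag-ID column and nonnegative
values.  Error models come from a JSON/YAML-free structured config dict:
either per-column ``{"q0":..,"q1":..,"q2":..}`` blocks or
``variance_columns`` naming companion columns holding explicit
per-observation variances.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dispersion import CountMatrix, DispersionFit
from .errors import ExplicitErrorModel, QuadraticErrorModel
from .plr import LRVVSet, PLRFit

__all__ = ["read_table", "parse_error_model_config", "write_plr_results",
           "write_dispersion_results"]


class TableParseError(ValueError):
    pass


def _read_frame(path, delimiter=None) -> pd.DataFrame:
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=delimiter)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TableParseError(f"cannot parse {path}: {exc}") from exc
    if df.columns.str.match(r"^Unnamed").all():
        raise TableParseError(f"{path}: missing header row")
    return df


def read_table(path, schema: str = "lrvv", delimiter=None):
    """Read a TSV/CSV table into an LRVVSet or CountMatrix.

    Delimiter is sniffed from the extension (.csv -> comma, else tab) and
    can be overridden.  Non-numeric or missing cells raise a parse error
    naming the offending cell.
    """
    df = _read_frame(path, delimiter)
    if schema == "lrvv":
        numeric = df.apply(pd.to_numeric, errors="coerce")
        _check_cells(numeric, df)
        return LRVVSet(numeric.to_numpy(float), columns=tuple(df.columns))
    if schema == "counts":
        if df.shape[1] < 3:
            raise TableParseError(
                "counts schema needs an ID column plus >= 2 replicate columns"
            )
        ids = df.iloc[:, 0].astype(str).tolist()
        numeric = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
        _check_cells(numeric, df.iloc[:, 1:])
        vals = numeric.to_numpy(float)
        if np.any(vals < 0):
            i, j = np.argwhere(vals < 0)[0]
            raise TableParseError(
                f"negative count at row {i + 1}, column {numeric.columns[j]!r}"
            )
        return CountMatrix(vals, tag_ids=tuple(ids))
    raise ValueError(f"unknown schema {schema!r}")


def _check_cells(numeric: pd.DataFrame, raw: pd.DataFrame) -> None:
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise TableParseError(
            f"non-numeric cell {raw.iloc[i, j]!r} at row {i + 1}, "
            f"column {raw.columns[j]!r}"
        )


def parse_error_model_config(cfg: dict, table: LRVVSet = None):
    """Build an error model from a structured config block.

    Accepted forms::

        {"q0": 1.0, "q1": 0.0, "q2": 0.01}          # shared quadratic
        {"columns": [{"q0":..}, {"q0":..}, ...]}     # per-column quadratic
        {"variance_columns": ["sx2", "sy2"]}         # explicit variances,
                                                     # taken from `table`
    """
    if "variance_columns" in cfg:
        if table is None:
            raise ValueError("variance_columns requires the input table")
        names = cfg["variance_columns"]
        idx = [table.columns.index(c) for c in names]
        return ExplicitErrorModel(table.data[:, idx])
    if "columns" in cfg:
        return [QuadraticErrorModel(c.get("q0", 0.0), c.get("q1", 0.0),
                                    c.get("q2", 0.0)) for c in cfg["columns"]]
    return QuadraticErrorModel(cfg.get("q0", 0.0), cfg.get("q1", 0.0),
                               cfg.get("q2", 0.0))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_plr_results(fit: PLRFit, path) -> None:
    """Serialize a PLR fit to schema-versioned JSON (full double precision)."""
    payload = {
        "schema": "plreg.plr_fit/1",
        "weights": fit.tau_result.weights.w.tolist(),
        "cve": fit.tau_result.cve,
        "kappa_tau": fit.tau_result.kappa_tau,
        "intercept": fit.line.intercept.tolist(),
        "slope": fit.line.slope.tolist(),
        "pairwise_slope": fit.pairwise_slope.tolist(),
        "r_vector": fit.r_vector.tolist(),
        "r_plr": fit.r_plr,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify))


def write_dispersion_results(fit: DispersionFit, json_path,
                             per_tag_path=None, tag_ids=None) -> None:
    """Serialize a dispersion fit: JSON summary plus per-tag TSV table."""
    q0, q1, q2 = fit.q
    payload = {
        "schema": "plreg.dispersion_fit/1",
        "q0": q0, "q1": q1, "q2": q2,
        "iterations": len(fit.trace) - 1,
        "converged": fit.converged,
        "excluded_fraction": fit.excluded_fraction,
        "flagged_tags": int(fit.mask_outlier.sum()),
        "trace": [list(t) for t in fit.trace],
    }
    Path(json_path).write_text(json.dumps(payload, indent=2, default=_jsonify))
    if per_tag_path is not None:
        n = len(fit.gbar)
        df = pd.DataFrame({
            "tag": list(tag_ids) if tag_ids is not None else list(range(n)),
            "gbar": fit.gbar,
            "msd": fit.msd,
            "delta_rms": fit.delta_rms,
            "zero_mean": fit.mask_zero_mean.astype(int),
            "high_mean": fit.mask_high_mean.astype(int),
            "outlier": fit.mask_outlier.astype(int),
        })
        df.to_csv(per_tag_path, sep="\t", index=False, float_format="%.10g")
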