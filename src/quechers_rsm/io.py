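"""Readers and writers for the pipeline's interchange files.

Everything rectangular travels as CSV (designs, recovery tables,
coefficient tables, deviation reports); factor-space configurations are
YAML; optimization results are JSON. All writers round-trip with their
readers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .basis import term_names
from .design import FactorSpace

__all__ = [
    "read_factor_config",
    "write_factor_config",
    "write_design",
    "read_design",
    "write_recoveries",
    "read_recoveries",
    "parse_coefficient_frame",
    "read_coefficient_table",
    "write_coefficient_table",
    "write_optimization_result",
]


# -- factor-space configuration -------------------------------------------


def read_factor_config(path) -> FactorSpace:
    """Load a factor space from a YAML config (ordered list of factors)."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if not payload or "factors" not in payload:
        raise ValueError(f"{path}: config must contain a 'factors' list")
    return FactorSpace.from_dict(payload)


def write_factor_config(space: FactorSpace, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(space.as_dict(), fh, sort_keys=False)


# -- designs and recovery tables ------------------------------------------


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, index=False)


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"run_id", "point_type"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: design CSV must contain {sorted(required)}")
    return df


def write_recoveries(observations: pd.DataFrame, path) -> None:
    out = observations.copy()
    out.insert(0, "run_id", observations.index)
    out.to_csv(path, index=False)


def read_recoveries(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "run_id" not in df.columns:
        raise ValueError(f"{path}: recovery CSV must contain a run_id column")
    return df.set_index("run_id")


# -- coefficient tables ----------------------------------------------------


def parse_coefficient_frame(
    frame: pd.DataFrame, factor_names: list[str]
) -> dict[str, tuple[np.ndarray, list[str], float | None]]:
    """Parse a long coefficient table into per-compound vectors.

    Expects columns ``compound``, ``term``, ``coefficient``, ``letter``;
    per compound there must be one row per basis term (named exactly as the
    basis labels them) plus optionally one ``R`` row. Returns
    ``compound -> (coefficients, letters, R)`` in basis order.
    """
    expected = term_names(factor_names)
    out: dict[str, tuple[np.ndarray, list[str], float | None]] = {}
    for compound, grp in frame.groupby("compound", sort=False):
        by_term = {row["term"]: row for _, row in grp.iterrows()}
        missing = [t for t in expected if t not in by_term]
        if missing:
            raise ValueError(
                f"compound {compound!r}: missing coefficient rows for {missing}"
            )
        unknown = sorted(set(by_term) - set(expected) - {"R"})
        if unknown:
            raise ValueError(
                f"compound {compound!r}: unknown term labels {unknown}"
            )
        coef = np.array([float(by_term[t]["coefficient"]) for t in expected])
        letters = [str(by_term[t].get("letter", "") or "") for t in expected]
        r = float(by_term["R"]["coefficient"]) if "R" in by_term else None
        out[compound] = (coef, letters, r)
    return out


def read_coefficient_table(path, factor_names: list[str]):
    """Read a coefficient CSV; see :func:`parse_coefficient_frame`."""
    frame = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    required = {"compound", "term", "coefficient"}
    if not required <= set(frame.columns):
        raise ValueError(f"{path}: coefficient CSV must contain {sorted(required)}")
    return parse_coefficient_frame(frame, factor_names)


def write_coefficient_table(models: dict, path, system: str = "") -> None:
    """Write fitted models as a long CSV mirroring the published layout.

    One row per term per compound (term, coefficient, letter) plus an ``R``
    row; reads back bit-identically through :func:`read_coefficient_table`
    (full-precision repr formatting).
    """
    rows = []
    for compound, model in models.items():
        letters = model.letters_ or [""] * len(model.coef_)
        for term, coef, letter in zip(model.term_names_, model.coef_, letters):
            rows.append(
                {
                    "system": system,
                    "compound": compound,
                    "term": term,
                    "coefficient": repr(float(coef)),
                    "letter": letter,
                }
            )
        if model.r_ is not None:
            rows.append(
                {
                    "system": system,
                    "compound": compound,
                    "term": "R",
                    "coefficient": repr(float(model.r_)),
                    "letter": "",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# -- optimization results --------------------------------------------------


def write_optimization_result(result, path) -> None:
    payload = {
        "system": result.system,
        "feasible": bool(result.feasible),
        "target": result.target,
        "tolerance": result.tolerance,
        "objective_value": result.objective_value,
        "conditions_natural": result.conditions_natural,
        "conditions_coded": [float(v) for v in result.conditions_coded],
        "predictions": result.predictions,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
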