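"""Multi-response optimization of extraction conditions.

The goal is a single set of extraction conditions at which every compound's
predicted recovery sits within a tolerance band around a target (100%).
Because the recovery surfaces are degree-3 polynomials that can carry
multiple maxima and minima, a dense grid scan of the coded cube comes
first (global), followed by a derivative-free simplex polish (local). Among
feasible points, a secondary criterion selects the *minimum* values of the
experimental variables — less soil, solvent, water and time for the same
predicted performance — implemented as minimizing the unweighted sum of
per-factor positions scaled to [0, 1] from each low bound.

The search never leaves the coded cube: empirical polynomial models are not
trusted outside the studied region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .basis import expand_terms
from .design import FactorSpace
from .model import RecoveryPolynomial

__all__ = ["OptimizationResult", "optimize_conditions", "predict_all"]

#: Penalty weight pushing the simplex polish back into the feasible band.
_PENALTY = 1e4


@dataclass
class OptimizationResult:
    """Optimized extraction conditions with their predicted recoveries."""

    conditions_coded: np.ndarray
    conditions_natural: dict[str, float]
    predictions: dict[str, float]
    feasible: bool
    objective_value: float  # max over compounds of |prediction - target|
    target: float
    tolerance: float
    system: str | None = None

    def summary(self) -> str:
        lines = [
            f"feasible: {self.feasible} "
            f"(max |pred - {self.target:g}| = {self.objective_value:.2f}, "
            f"tolerance {self.tolerance:g})"
        ]
        for name, value in self.conditions_natural.items():
            lines.append(f"  {name} = {value:.3g}")
        for compound, pred in self.predictions.items():
            lines.append(f"  {compound}: {pred:.1f}%")
        return "\n".join(lines)


def _coef_matrix(models: dict[str, RecoveryPolynomial]) -> np.ndarray:
    sizes = {m.coef_.size for m in models.values()}
    if len(sizes) != 1:
        raise ValueError(f"models carry inconsistent basis sizes: {sizes}")
    return np.column_stack([m.coef_ for m in models.values()])


def _max_abs_dev(coded: np.ndarray, B: np.ndarray, target: float) -> np.ndarray:
    """max_c |prediction_c - target| for one point or a batch."""
    preds = expand_terms(coded) @ B
    return np.max(np.abs(preds - target), axis=-1)


def optimize_conditions(
    models: dict[str, RecoveryPolynomial],
    space: FactorSpace,
    target: float = 100.0,
    tolerance: float = 2.5,
    minimize_variables: bool = True,
    grid_points: int = 21,
    system: str | None = None,
) -> OptimizationResult:
    """Find extraction conditions driving all predicted recoveries to target.

    Lexicographic solve: (1) scan a ``grid_points``-per-axis grid of the
    coded cube for points where every compound's predicted recovery lies
    within ``target +/- tolerance``; (2) among feasible points, minimize
    the sum of per-factor scaled positions (x - low)/(high - low)
    (``minimize_variables=True``), refining with a Nelder-Mead polish under
    a feasibility penalty. If no point is feasible, the point minimizing
    the worst-case deviation ``max_c |pred_c - target|`` is returned with
    ``feasible=False``.
    """
    if not models:
        raise ValueError("need at least one model to optimize")
    k = len(space)
    for name, m in models.items():
        if m.n_features_in_ != k:
            raise ValueError(
                f"model {name!r} expects {m.n_features_in_} factors, "
                f"space has {k}"
            )
    B = _coef_matrix(models)

    axis = np.linspace(-1.0, 1.0, grid_points)
    # scaled position in [0,1] from the low bound; coded -1 maps to 0
    def sum_scaled(coded: np.ndarray) -> np.ndarray:
        return np.sum((np.atleast_2d(coded) + 1.0) / 2.0, axis=-1)

    best_dev = np.inf
    best_dev_point = np.zeros(k)
    best_feas_score = np.inf
    best_feas_point: np.ndarray | None = None

    def process(P: np.ndarray) -> None:
        nonlocal best_dev, best_dev_point, best_feas_score, best_feas_point
        dev = _max_abs_dev(P, B, target)
        i = int(np.argmin(dev))
        if dev[i] < best_dev:
            best_dev = float(dev[i])
            best_dev_point = P[i]
        feas = dev <= tolerance
        if feas.any():
            scores = np.where(
                feas,
                sum_scaled(P) if minimize_variables else dev,
                np.inf,
            )
            j = int(np.argmin(scores))
            if scores[j] < best_feas_score:
                best_feas_score = float(scores[j])
                best_feas_point = P[j]

    # full grid, evaluated in chunks to bound the expanded-basis memory
    grid = np.stack(
        np.meshgrid(*([axis] * k), indexing="ij"), axis=-1
    ).reshape(-1, k)
    for start in range(0, grid.shape[0], 200_000):
        process(grid[start : start + 200_000])

    feasible = best_feas_point is not None
    if feasible:
        x0 = best_feas_point

        def objective(x: np.ndarray) -> float:
            x = np.clip(x, -1.0, 1.0)
            dev = float(_max_abs_dev(x, B, target))
            score = float(sum_scaled(x)[0]) if minimize_variables else dev
            return score + _PENALTY * max(0.0, dev - tolerance)

    else:
        x0 = best_dev_point

        def objective(x: np.ndarray) -> float:
            x = np.clip(x, -1.0, 1.0)
            return float(_max_abs_dev(x, B, target))

    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        bounds=[(-1.0, 1.0)] * k,
        options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 5000},
    )
    x = np.clip(res.x, -1.0, 1.0)
    # keep the polish only if it did not break feasibility
    if feasible and float(_max_abs_dev(x, B, target)) > tolerance + 1e-9:
        x = x0
    elif not feasible and objective(x) > objective(x0):
        x = x0

    preds = expand_terms(x) @ B
    natural = space.decode(x)
    return OptimizationResult(
        conditions_coded=x,
        conditions_natural=dict(zip(space.names, natural.tolist())),
        predictions={c: float(p) for c, p in zip(models, preds)},
        feasible=feasible,
        objective_value=float(np.max(np.abs(preds - target))),
        target=target,
        tolerance=tolerance,
        system=system,
    )


def predict_all(
    models: dict[str, RecoveryPolynomial],
    conditions_natural,
    space: FactorSpace,
) -> dict[str, float]:
    """Predicted recovery per compound at natural-unit conditions.

    Conditions may be a mapping keyed by factor name or a vector in the
    space's factor order; values outside the studied ranges raise an
    extrapolation warning from the encoder.
    """
    if isinstance(conditions_natural, dict):
        missing = [n for n in space.names if n not in conditions_natural]
        if missing:
            raise KeyError(f"conditions missing factors: {missing}")
        vec = [conditions_natural[n] for n in space.names]
    else:
        vec = list(conditions_natural)
    coded = space.encode(vec)
    return {name: float(m.predict(coded)) for name, m in models.items()}
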