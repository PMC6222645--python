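"""Synthetic recovery tables and calibration series.

The per-run recoveries behind the published models live in an appendix that
is not reproduced with the article, so every pipeline stage is exercised on
synthetic data carrying the statistical structure the analysis assumes: a
45-run face-centred composite design per extraction system, recoveries
generated from a known 31-coefficient vector (by default the published
citrate/acetate vectors, so simulations inhabit the actual surface
geometry) plus homoscedastic Gaussian noise, clipped below at 0%.

The default noise level is 2 recovery points — commensurate with the
full-model residual ranges the published deviation audit reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import FactorSpace, coded_matrix, generate_ccf_design
from .model import predict_recovery

__all__ = ["SimulationSpec", "RecoveryTable", "simulate_recoveries", "simulate_calibration"]


@dataclass
class RecoveryTable:
    """A design together with observed recovery % per run and compound."""

    design: pd.DataFrame
    observations: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.design) != len(self.observations):
            raise ValueError(
                f"design has {len(self.design)} runs, observations "
                f"{len(self.observations)}"
            )
        obs = self.observations.to_numpy(dtype=float)
        if not np.all(np.isfinite(obs)) or np.any(obs < 0):
            raise ValueError("recoveries must be finite and non-negative")

    @property
    def compounds(self) -> list[str]:
        return list(self.observations.columns)


@dataclass
class SimulationSpec:
    """Conditions for generating a synthetic recovery table."""

    space: FactorSpace
    true_coefficients: dict[str, np.ndarray]
    n_center: int = 3
    noise_sd: float = 2.0
    seed: int | None = None
    clip_low: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        from .basis import n_terms

        expected = n_terms(len(self.space))
        for name, coef in self.true_coefficients.items():
            coef = np.asarray(coef, dtype=float)
            if coef.size != expected:
                raise ValueError(
                    f"coefficient vector for {name!r} has {coef.size} terms, "
                    f"expected {expected}"
                )
            self.true_coefficients[name] = coef


def simulate_recoveries(spec: SimulationSpec) -> RecoveryTable:
    """Generate a recovery table: polynomial truth plus Gaussian noise.

    For each design run and compound, ``Y = f(coded; true_coefficients) +
    N(0, noise_sd^2)``, clipped below at ``clip_low``. Deterministic given
    the seed.
    """
    design = generate_ccf_design(spec.space, n_center=spec.n_center)
    X = coded_matrix(design)
    rng = np.random.default_rng(spec.seed)
    data = {}
    for compound, coef in spec.true_coefficients.items():
        clean = predict_recovery(coef, X)
        noisy = clean + rng.normal(0.0, spec.noise_sd, size=len(X))
        data[compound] = np.maximum(noisy, spec.clip_low)
    observations = pd.DataFrame(data, index=design["run_id"].to_numpy())
    return RecoveryTable(design=design, observations=observations)


def simulate_calibration(
    slope_solvent: float,
    me_true: float,
    n_levels: int = 5,
    noise_sd: float = 0.0,
    seed: int | None = None,
    compound: str = "synthetic",
    combination: str = "none",
    linear_range: tuple[float, float] = (0.005, 0.1),
    intercept: float = 0.0,
):
    """Paired solvent/matrix calibration series with a known matrix effect.

    The matrix slope is ``slope_solvent * (1 + me_true/100)``; responses at
    ``n_levels`` evenly spaced concentrations across the linear range get
    additive Gaussian noise. Returns ``(solvent, matrix)`` series.
    """
    from .matrix_effect import CalibrationSeries

    if n_levels < 3:
        raise ValueError("need at least 3 calibration levels")
    conc = np.linspace(linear_range[0], linear_range[1], n_levels)
    rng = np.random.default_rng(seed)
    slope_matrix = slope_solvent * (1.0 + me_true / 100.0)
    series = []
    for medium, slope in (("solvent", slope_solvent), ("matrix", slope_matrix)):
        resp = intercept + slope * conc + rng.normal(0.0, noise_sd, size=n_levels)
        series.append(
            CalibrationSeries(
                compound=compound,
                medium=medium,
                concentrations=conc,
                responses=resp,
                combination=combination,
                linear_range=linear_range,
            )
        )
    return tuple(series)
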