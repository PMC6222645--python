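"""LC-MS matrix effect from calibration slope comparison.

Electrospray ionization is sensitive to co-eluting matrix components: the
same analyte concentration can give a suppressed or enhanced signal in a
soil extract relative to pure solvent. The matrix effect is quantified by
comparing calibration slopes,

    ME(%) = (S_m - S_s) / S_s * 100,

where S_m is the slope in matrix extract and S_s the slope in solvent.
Negative ME is ionization suppression, positive is enhancement, and
|ME| > 20% is conventionally treated as analytically significant (a fixed
rule, not a statistical test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

__all__ = [
    "LINEAR_RANGE",
    "ME_SIGNIFICANCE_THRESHOLD",
    "CalibrationSeries",
    "MatrixEffectResult",
    "fit_calibration_slope",
    "compute_matrix_effect",
    "me_panel",
]

#: Default linear calibration range, mg/L.
LINEAR_RANGE: tuple[float, float] = (0.005, 0.1)

#: |ME| (%) above which the effect is flagged as significant.
ME_SIGNIFICANCE_THRESHOLD: float = 20.0


@dataclass
class CalibrationSeries:
    """Calibration points for one compound in one medium.

    Points are (concentration mg/L, instrument response) pairs; at least
    three points with a nonzero concentration spread are required, and
    concentrations should lie inside the declared linear range.
    """

    compound: str
    medium: str  # "solvent" or "matrix"
    concentrations: np.ndarray
    responses: np.ndarray
    combination: str = "none"  # clean-up: none / PSA / PSA-C18
    linear_range: tuple[float, float] = LINEAR_RANGE

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.medium not in ("solvent", "matrix"):
            raise ValueError(f"medium must be 'solvent' or 'matrix', got {self.medium!r}")
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses must align")
        if self.concentrations.size < 3:
            raise ValueError("a calibration series needs at least 3 points")
        order = np.argsort(self.concentrations)
        self.concentrations = self.concentrations[order]
        self.responses = self.responses[order]
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be distinct")
        lo, hi = self.linear_range
        eps = 1e-12
        if self.concentrations[0] < lo - eps or self.concentrations[-1] > hi + eps:
            raise ValueError(
                f"concentrations outside the linear range {self.linear_range}"
            )


@dataclass
class MatrixEffectResult:
    """Slope comparison for one compound/clean-up combination."""

    compound: str
    slope_matrix: float
    slope_solvent: float
    me_percent: float
    significant: bool
    direction: str  # suppression / enhancement / none
    combination: str = "none"


def fit_calibration_slope(series: CalibrationSeries) -> float:
    """Ordinary least-squares slope of response on concentration.

    The intercept is estimated, not forced through zero, so baseline
    offsets do not bias the slope.
    """
    if np.ptp(series.concentrations) <= 0:
        raise ValueError("zero concentration spread")
    return float(linregress(series.concentrations, series.responses).slope)


def compute_matrix_effect(
    slope_matrix: float,
    slope_solvent: float,
    compound: str = "",
    combination: str = "none",
) -> MatrixEffectResult:
    """Matrix effect from a matrix/solvent slope pair."""
    if slope_solvent == 0:
        raise ValueError("solvent slope must be nonzero")
    me = (slope_matrix - slope_solvent) / slope_solvent * 100.0
    if me < 0:
        direction = "suppression"
    elif me > 0:
        direction = "enhancement"
    else:
        direction = "none"
    return MatrixEffectResult(
        compound=compound,
        slope_matrix=float(slope_matrix),
        slope_solvent=float(slope_solvent),
        me_percent=float(me),
        significant=abs(me) > ME_SIGNIFICANCE_THRESHOLD,
        direction=direction,
        combination=combination,
    )


def me_panel(series: list[CalibrationSeries]) -> pd.DataFrame:
    """Matrix-effect table across compounds and clean-up combinations.

    Every (compound, combination) group must contain exactly one solvent
    and one matrix series; a missing half raises an error naming the gap.
    """
    groups: dict[tuple[str, str], dict[str, CalibrationSeries]] = {}
    for s in series:
        key = (s.compound, s.combination)
        slot = groups.setdefault(key, {})
        if s.medium in slot:
            raise ValueError(
                f"duplicate {s.medium} series for {s.compound!r} / {s.combination!r}"
            )
        slot[s.medium] = s

    rows = []
    for (compound, combination), slot in groups.items():
        for medium in ("solvent", "matrix"):
            if medium not in slot:
                raise ValueError(
                    f"missing {medium} series for compound {compound!r}, "
                    f"combination {combination!r}"
                )
        result = compute_matrix_effect(
            fit_calibration_slope(slot["matrix"]),
            fit_calibration_slope(slot["solvent"]),
            compound=compound,
            combination=combination,
        )
        rows.append(
            {
                "compound": compound,
                "combination": combination,
                "slope_solvent": result.slope_solvent,
                "slope_matrix": result.slope_matrix,
                "me_percent": result.me_percent,
                "significant": result.significant,
                "direction": result.direction,
            }
        )
    return pd.DataFrame(rows)
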