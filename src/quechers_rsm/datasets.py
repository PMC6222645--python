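"""Published model coefficients, factor ranges and optimized conditions.

The package ships the full citrate and acetate polynomial models (31
coefficients, significance letters and R per compound) and the optimized
extraction conditions selected for each system, so the prediction, pruning
and optimization stages can run without refitting.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .design import FactorSpace
from .io import parse_coefficient_frame
from .model import RecoveryPolynomial

__all__ = [
    "SYSTEMS",
    "COMPOUNDS",
    "load_published_models",
    "published_factor_space",
    "published_conditions",
]

SYSTEMS = ("citrate", "acetate")

#: Compound order used throughout the published tables.
COMPOUNDS = (
    "alloxydim",
    "sethoxydim",
    "profoxydim",
    "deallyloxylated-alloxydim",
    "deethoxylated-sethoxydim",
    "sethoxydim-oxazole",
)

#: Optimized extraction conditions per system (natural units, factor order
#: SW g, AM %, EV mL, WC mL, ET min).
OPTIMIZED_CONDITIONS: dict[str, dict[str, float]] = {
    "citrate": {"SW": 3.23, "AM": 52.8, "EV": 8.0, "WC": 3.8, "ET": 1.8},
    "acetate": {"SW": 3.96, "AM": 57.0, "EV": 9.4, "WC": 4.0, "ET": 2.8},
}


def _fixture_frame(system: str) -> pd.DataFrame:
    if system not in SYSTEMS:
        raise ValueError(f"unknown system {system!r}; expected one of {SYSTEMS}")
    path = resources.files("quechers_rsm.data") / f"{system}_model.csv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, keep_default_na=False, float_precision="round_trip")


def load_published_models(system: str) -> dict[str, RecoveryPolynomial]:
    """Published polynomial models for one extraction system.

    Returns an ordered mapping compound -> :class:`RecoveryPolynomial`
    built from the shipped coefficient table, with significance letters and
    the published R attached.
    """
    frame = _fixture_frame(system)
    space = published_factor_space()
    parsed = parse_coefficient_frame(frame, factor_names=space.names)
    models = {}
    for compound in COMPOUNDS:
        coef, letters, r = parsed[compound]
        models[compound] = RecoveryPolynomial.from_coefficients(
            coef, factor_names=space.names, letters=letters, r=r
        )
    return models


def published_factor_space() -> FactorSpace:
    """The five-factor extraction space with its published working ranges."""
    return FactorSpace.default()


def published_conditions(system: str) -> dict[str, float]:
    """Optimized extraction conditions selected for a system (natural units)."""
    if system not in OPTIMIZED_CONDITIONS:
        raise ValueError(f"unknown system {system!r}; expected one of {SYSTEMS}")
    return dict(OPTIMIZED_CONDITIONS[system])
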