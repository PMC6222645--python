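"""Factor spaces and face-centred central composite (CCF) designs.

The extraction experiments vary five factors — soil weight (SW), the
acetonitrile/methanol proportion of the extraction solvent (AM), extraction
solvent volume (EV), water content (WC) and extraction time (ET) — each over
a natural-unit working range. All modelling happens on *coded* variables,
the linear map of each factor onto [-1, +1], so that fitted coefficients are
directly comparable across factors.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Factor",
    "FactorSpace",
    "DEFAULT_RANGES",
    "build_factor_space",
    "encode",
    "decode",
    "generate_ccf_design",
    "coded_matrix",
]

#: Published working ranges, in canonical factor order (SW, AM, EV, WC, ET).
DEFAULT_RANGES: tuple[tuple[str, str, float, float], ...] = (
    ("SW", "g", 2.4, 5.8),
    ("AM", "%", 5.0, 95.0),
    ("EV", "mL", 8.0, 16.0),
    ("WC", "mL", 1.5, 4.5),
    ("ET", "min", 1.0, 3.0),
)


@dataclass(frozen=True)
class Factor:
    """A single experimental variable with its natural-unit range."""

    name: str
    unit: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.low) or not np.isfinite(self.high):
            raise ValueError(f"factor {self.name!r}: bounds must be finite")
        if not self.low < self.high:
            raise ValueError(
                f"factor {self.name!r}: low ({self.low}) must be strictly "
                f"below high ({self.high})"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)


class FactorSpace:
    """Ordered collection of factors with coding/decoding rules.

    Coding maps natural units linearly onto [-1, +1]:
    ``coded = (natural - center) / half_range``.

    Parameters
    ----------
    factors
        Iterable of ``(name, unit, low, high)`` tuples (or :class:`Factor`
        instances) in the order the design columns should follow.
    """

    def __init__(self, factors: Iterable[Factor | tuple]) -> None:
        parsed = [f if isinstance(f, Factor) else Factor(*f) for f in factors]
        if not parsed:
            raise ValueError("a factor space needs at least one factor")
        names = [f.name for f in parsed]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate factor names: {names}")
        self.factors: tuple[Factor, ...] = tuple(parsed)

    @classmethod
    def default(cls) -> "FactorSpace":
        """The published five-factor extraction space."""
        return cls(DEFAULT_RANGES)

    def __len__(self) -> int:
        return len(self.factors)

    def __repr__(self) -> str:
        parts = ", ".join(
            f"{f.name}[{f.low}-{f.high} {f.unit}]" for f in self.factors
        )
        return f"FactorSpace({parts})"

    def __eq__(self, other: object) -> bool:
        return isinstance(other, FactorSpace) and self.factors == other.factors

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def units(self) -> list[str]:
        return [f.unit for f in self.factors]

    @property
    def lows(self) -> np.ndarray:
        return np.array([f.low for f in self.factors])

    @property
    def highs(self) -> np.ndarray:
        return np.array([f.high for f in self.factors])

    @property
    def centers(self) -> np.ndarray:
        return np.array([f.center for f in self.factors])

    @property
    def half_ranges(self) -> np.ndarray:
        return np.array([f.half_range for f in self.factors])

    def encode(self, natural: Sequence[float] | np.ndarray) -> np.ndarray:
        """Map natural-unit values to coded [-1, +1] units.

        Accepts a single point (length-k vector) or an (n, k) array of
        points. Out-of-range values are permitted — polynomial models can
        be *evaluated* outside the studied region — but raise a warning
        because such predictions are extrapolations.
        """
        natural = np.asarray(natural, dtype=float)
        k = len(self)
        if natural.shape[-1] != k:
            raise ValueError(
                f"expected {k} factor values, got {natural.shape[-1]}"
            )
        coded = (natural - self.centers) / self.half_ranges
        if np.any(np.abs(coded) > 1 + 1e-12):
            warnings.warn(
                "natural values outside the studied factor ranges; "
                "coded coordinates fall outside [-1, +1] (extrapolation)",
                stacklevel=2,
            )
        return coded

    def decode(self, coded: Sequence[float] | np.ndarray) -> np.ndarray:
        """Inverse of :meth:`encode`: coded units back to natural units."""
        coded = np.asarray(coded, dtype=float)
        if coded.shape[-1] != len(self):
            raise ValueError(
                f"expected {len(self)} coded values, got {coded.shape[-1]}"
            )
        return self.centers + coded * self.half_ranges

    def as_dict(self) -> dict:
        return {
            "factors": [
                {"name": f.name, "unit": f.unit, "low": f.low, "high": f.high}
                for f in self.factors
            ]
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "FactorSpace":
        return cls(
            (f["name"], f["unit"], float(f["low"]), float(f["high"]))
            for f in payload["factors"]
        )


def build_factor_space(ranges: Iterable[tuple]) -> FactorSpace:
    """Build a :class:`FactorSpace` from ``(name, unit, low, high)`` tuples."""
    return FactorSpace(ranges)


def encode(space: FactorSpace, natural) -> np.ndarray:
    return space.encode(natural)


def decode(space: FactorSpace, coded) -> np.ndarray:
    return space.decode(coded)


def generate_ccf_design(space: FactorSpace, n_center: int = 3) -> pd.DataFrame:
    """Generate a face-centred central composite design.

    The design consists of a full 2^k factorial (all +/-1 corners, in
    lexicographic order with -1 before +1), 2k axial points on the face
    centres (alpha = 1, one factor at a time, low face first) and
    ``n_center`` replicated centre runs — ``2**k + 2*k + n_center`` runs
    for k factors.

    Returns
    -------
    pandas.DataFrame
        One row per run with columns ``run_id``, ``point_type``, a coded
        column ``x_<name>`` and a natural-unit column ``<name>`` per factor.
        The factor space is attached as ``df.attrs["factor_space"]``.
    """
    k = len(space)
    if k == 0:
        raise ValueError("cannot generate a design for zero factors")
    if n_center < 1:
        raise ValueError("n_center must be >= 1")

    rows: list[np.ndarray] = []
    types: list[str] = []
    for corner in itertools.product((-1.0, 1.0), repeat=k):
        rows.append(np.array(corner))
        types.append("factorial")
    for i in range(k):
        for level in (-1.0, 1.0):
            point = np.zeros(k)
            point[i] = level
            rows.append(point)
            types.append("axial")
    for _ in range(n_center):
        rows.append(np.zeros(k))
        types.append("center")

    coded = np.vstack(rows)
    natural = space.decode(coded)
    df = pd.DataFrame({"run_id": np.arange(1, len(rows) + 1), "point_type": types})
    for j, name in enumerate(space.names):
        df[f"x_{name}"] = coded[:, j]
    for j, name in enumerate(space.names):
        df[name] = natural[:, j]
    df.attrs["factor_space"] = space
    return df


def coded_matrix(design: pd.DataFrame) -> np.ndarray:
    """Extract the (n_runs, k) coded matrix from a design frame."""
    cols = [c for c in design.columns if c.startswith("x_")]
    if not cols:
        raise ValueError("design frame has no coded columns (x_<name>)")
    return design[cols].to_numpy(dtype=float)
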