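"""Significance-based term pruning and the deviation audit.

Dropping "non-significant" terms from an empirical polynomial is common
practice, but whether the truncated equation still tracks the data must be
demonstrated, not assumed: the goodness-of-fit statistic R alone can hide
large pointwise errors. This module prunes a fitted recovery model at a
minimum confidence level (keeping only terms flagged at or above that
level, the intercept always retained) and audits the result by the range of
absolute deviations between observed recoveries and the pruned model's
predictions, per run.

Two pruning modes exist: ``truncate`` (default) deletes terms but keeps the
remaining coefficients at their full-fit values, which is how a published
equation would actually be simplified; ``refit`` re-estimates the reduced
basis by least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import expand_terms
from .model import LETTER_CONFIDENCE, RecoveryPolynomial

__all__ = [
    "CONFIDENCE_LEVELS",
    "PrunedModel",
    "prune_model",
    "deviation_range",
    "selection_report",
]

#: Levels at which pruning is defined (% confidence; 0 keeps everything).
CONFIDENCE_LEVELS: tuple[int, ...] = (95, 90, 80, 70, 0)


@dataclass
class PrunedModel:
    """A recovery model restricted to terms meeting a confidence level."""

    parent: RecoveryPolynomial
    min_confidence: int
    mode: str
    retained: np.ndarray  # boolean mask over the basis
    coef_: np.ndarray  # full-length vector; pruned terms zeroed
    deviation_min: float | None = None
    deviation_max: float | None = None
    r_pruned: float | None = None
    retained_terms: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        out = expand_terms(np.atleast_2d(X)) @ self.coef_
        return float(out[0]) if single else out


def _retained_mask(letters: list[str], min_confidence: int) -> np.ndarray:
    """Boolean mask of terms whose letter meets the level; intercept kept."""
    mask = np.array(
        [LETTER_CONFIDENCE[let] >= min_confidence for let in letters], dtype=bool
    )
    mask[0] = True
    return mask


def prune_model(
    model: RecoveryPolynomial,
    min_confidence: int,
    mode: str = "truncate",
    X=None,
    y=None,
) -> PrunedModel:
    """Prune a fitted model at a minimum confidence level.

    Parameters
    ----------
    model
        A fitted :class:`RecoveryPolynomial` (or one built from published
        coefficients with significance letters attached).
    min_confidence
        One of 95, 90, 80, 70 or 0 (%): retain terms flagged at this
        confidence or stricter. Level 0 retains all terms.
    mode
        ``"truncate"`` keeps the full-fit values of retained coefficients;
        ``"refit"`` re-estimates the reduced basis (requires the training
        data, taken from the fit or passed via ``X``/``y``).
    """
    if min_confidence not in CONFIDENCE_LEVELS:
        raise ValueError(
            f"min_confidence must be one of {CONFIDENCE_LEVELS}, "
            f"got {min_confidence}"
        )
    if mode not in ("truncate", "refit"):
        raise ValueError(f"mode must be 'truncate' or 'refit', got {mode!r}")
    if model.letters_ is None:
        raise ValueError("model carries no significance letters; cannot prune")

    mask = _retained_mask(model.letters_, min_confidence)
    coef = np.where(mask, model.coef_, 0.0)

    if mode == "refit" and min_confidence != 0:
        if X is None or y is None:
            X = getattr(model, "_X_fit", None)
            y = getattr(model, "_y_fit", None)
        if X is None or y is None:
            raise ValueError("refit mode needs the design matrix and recoveries")
        F = expand_terms(np.asarray(X, dtype=float))[:, mask]
        beta, *_ = np.linalg.lstsq(F, np.asarray(y, dtype=float), rcond=None)
        coef = np.zeros_like(model.coef_)
        coef[mask] = beta

    return PrunedModel(
        parent=model,
        min_confidence=min_confidence,
        mode=mode,
        retained=mask,
        coef_=coef,
        retained_terms=[t for t, m in zip(model.term_names_, mask) if m],
    )


def deviation_range(pruned: PrunedModel, X, y) -> tuple[float, float]:
    """(min, max) of per-run absolute deviations |predicted - observed|.

    Deviations are in recovery percentage points. The results are stored on
    the pruned model (``deviation_min``/``deviation_max``) along with
    ``r_pruned``, the Pearson correlation between predictions and
    observations (the conventional R once terms have been deleted, since
    the R-squared formula can go negative for a truncated equation).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError(
            f"design has {X.shape[0]} runs but observations have {y.shape[0]}"
        )
    pred = pruned.predict(X)
    dev = np.abs(pred - y)
    pruned.deviation_min = float(dev.min())
    pruned.deviation_max = float(dev.max())
    if np.std(pred) > 0 and np.std(y) > 0:
        pruned.r_pruned = float(np.corrcoef(pred, y)[0, 1])
    else:
        pruned.r_pruned = float("nan")
    return pruned.deviation_min, pruned.deviation_max


def selection_report(
    models: dict[str, RecoveryPolynomial],
    X,
    observations: pd.DataFrame,
    levels: tuple[int, ...] = CONFIDENCE_LEVELS,
    mode: str = "truncate",
) -> pd.DataFrame:
    """Deviation-range audit across compounds and confidence levels.

    Returns one row per compound x level with the deviation range and the
    pruned model's R. All models must share the same design; observations
    are a runs x compounds frame.
    """
    X = np.asarray(X, dtype=float)
    rows = []
    for compound, model in models.items():
        if compound not in observations.columns:
            raise KeyError(f"no observations for compound {compound!r}")
        y = observations[compound].to_numpy(dtype=float)
        for level in levels:
            pruned = prune_model(model, level, mode=mode)
            dmin, dmax = deviation_range(pruned, X, y)
            rows.append(
                {
                    "compound": compound,
                    "confidence_level": level,
                    "n_terms": pruned.n_retained,
                    "deviation_min": dmin,
                    "deviation_max": dmax,
                    "R": pruned.r_pruned,
                }
            )
    return pd.DataFrame(rows)
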