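"""Least-squares recovery models with coefficient inference.

Each compound's recovery surface is fitted independently by ordinary least
squares on the 31-term polynomial basis. Coefficient significance is
reported with the compact letter convention used throughout this workflow:
``a``/``b``/``c``/``d`` for two-sided coefficient t-test p-values below
0.05/0.10/0.20/0.30 (95/90/80/70% confidence), blank otherwise. Goodness of
fit is the multiple correlation coefficient R = sqrt(1 - SSE/SST).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .basis import expand_terms, n_terms, term_names

__all__ = [
    "significance_letter",
    "RecoveryPolynomial",
    "fit_full_model",
    "predict_recovery",
]

#: (p-value threshold, letter) pairs in increasing threshold order.
LETTER_THRESHOLDS: tuple[tuple[float, str], ...] = (
    (0.05, "a"),
    (0.10, "b"),
    (0.20, "c"),
    (0.30, "d"),
)

#: Confidence level (%) implied by each letter.
LETTER_CONFIDENCE: dict[str, int] = {"a": 95, "b": 90, "c": 80, "d": 70, "": 0}


def significance_letter(p: float) -> str:
    """Letter code for a two-sided p-value (``''`` when p >= 0.30)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value must lie in [0, 1], got {p}")
    for threshold, letter in LETTER_THRESHOLDS:
        if p < threshold:
            return letter
    return ""


class RecoveryPolynomial(RegressorMixin, BaseEstimator):
    """Polynomial recovery model on coded extraction factors.

    A scikit-learn style regressor: ``fit(X, y)`` takes the (n_runs, k)
    coded design matrix and the recovery vector (%), expands the design
    into the fixed polynomial basis and solves by ordinary least squares.

    Parameters
    ----------
    factor_names
        Optional factor labels used for printable term names; defaults to
        ``x0..x{k-1}``.

    Attributes
    ----------
    coef_ : ndarray of shape (n_terms,)
        Fitted coefficients, recovery % on the coded scale, in the fixed
        basis order (intercept first).
    standard_errors_, p_values_, letters_ : per-term inference.
    r_ : float
        Multiple correlation coefficient sqrt(1 - SSE/SST).
    sse_ : float
        Sum of squared residuals.
    residual_df_ : int
        n_runs - n_terms.
    """

    def __init__(self, factor_names: list[str] | None = None) -> None:
        self.factor_names = factor_names

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y) -> "RecoveryPolynomial":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D coded design matrix")
        n, k = X.shape
        if y.shape != (n,):
            raise ValueError(f"y must have shape ({n},), got {y.shape}")
        if not np.all(np.isfinite(y)):
            raise ValueError("recoveries must be finite")
        p = n_terms(k)
        if n <= p:
            raise ValueError(
                f"need more runs ({n}) than basis terms ({p}) to fit"
            )
        F = expand_terms(X)
        singvals = np.linalg.svd(F, compute_uv=False)
        if singvals[-1] < 1e-10 * singvals[0]:
            raise ValueError(
                "expanded design matrix is rank-deficient; the runs do not "
                "support the full polynomial basis"
            )

        res = sm.OLS(y, F).fit()
        self.n_features_in_ = k
        self.term_names_ = term_names(
            self.factor_names
            if self.factor_names is not None
            else [f"x{i}" for i in range(k)]
        )
        self.coef_ = np.asarray(res.params, dtype=float)
        self.standard_errors_ = np.asarray(res.bse, dtype=float)
        self.p_values_ = np.asarray(res.pvalues, dtype=float)
        self.letters_ = [significance_letter(pv) for pv in self.p_values_]
        self.sse_ = float(res.ssr)
        self.residual_df_ = int(res.df_resid)
        sst = float(np.sum((y - y.mean()) ** 2))
        self.r_ = float(np.sqrt(max(0.0, 1.0 - self.sse_ / sst))) if sst > 0 else 0.0
        # kept for refit-mode pruning
        self._X_fit = X
        self._y_fit = y
        return self

    @classmethod
    def from_coefficients(
        cls,
        coef,
        factor_names: list[str] | None = None,
        letters: list[str] | None = None,
        r: float | None = None,
    ) -> "RecoveryPolynomial":
        """Build a prediction-ready model from published coefficients.

        Inference attributes not supplied (standard errors, p-values) are
        left as ``None``; ``letters`` may carry published significance
        flags so the model can be pruned.
        """
        coef = np.asarray(coef, dtype=float)
        for k in range(1, 30):
            if n_terms(k) == coef.size:
                break
        else:
            raise ValueError(f"no factor count matches {coef.size} terms")
        model = cls(factor_names=factor_names)
        model.n_features_in_ = k
        model.coef_ = coef
        model.term_names_ = term_names(
            factor_names if factor_names is not None else [f"x{i}" for i in range(k)]
        )
        if letters is not None and len(letters) != coef.size:
            raise ValueError("letters length must match coefficient length")
        model.letters_ = list(letters) if letters is not None else None
        model.standard_errors_ = None
        model.p_values_ = None
        model.r_ = float(r) if r is not None else None
        model.sse_ = None
        model.residual_df_ = None
        return model

    # -- prediction --------------------------------------------------------

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        X2 = np.atleast_2d(X)
        if X2.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} coded factors, got {X2.shape[1]}"
            )
        out = expand_terms(X2) @ self.coef_
        return float(out[0]) if single else out

    # -- reporting ---------------------------------------------------------

    def summary_frame(self) -> pd.DataFrame:
        """Per-term table: name, coefficient, SE, p-value, letter."""
        check_is_fitted(self, "coef_")
        return pd.DataFrame(
            {
                "term": self.term_names_,
                "coefficient": self.coef_,
                "se": self.standard_errors_
                if self.standard_errors_ is not None
                else np.nan,
                "p_value": self.p_values_ if self.p_values_ is not None else np.nan,
                "letter": self.letters_ if self.letters_ is not None else "",
            }
        )


def fit_full_model(design, recoveries, compound: str) -> RecoveryPolynomial:
    """Fit one compound's full polynomial model from a design + recovery table.

    Parameters
    ----------
    design
        Design frame from :func:`~quechers_rsm.design.generate_ccf_design`
        (or any frame with ``x_<name>`` coded columns).
    recoveries
        DataFrame of recovery % with one column per compound, rows aligned
        with the design runs.
    compound
        Column to fit.
    """
    from .design import coded_matrix

    if len(recoveries) != len(design):
        raise ValueError(
            f"recovery table has {len(recoveries)} rows but the design has "
            f"{len(design)} runs"
        )
    if compound not in recoveries.columns:
        raise KeyError(f"unknown compound {compound!r}")
    X = coded_matrix(design)
    names = [c[2:] for c in design.columns if c.startswith("x_")]
    return RecoveryPolynomial(factor_names=names).fit(
        X, recoveries[compound].to_numpy(dtype=float)
    )


def predict_recovery(coefficients, coded) -> float | np.ndarray:
    """Inner product of a coefficient vector with the expanded basis."""
    coefficients = np.asarray(coefficients, dtype=float)
    features = expand_terms(np.asarray(coded, dtype=float))
    if features.shape[-1] != coefficients.size:
        raise ValueError(
            f"coefficient vector ({coefficients.size}) does not match basis "
            f"({features.shape[-1]})"
        )
    return features @ coefficients
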