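"""The polynomial term basis for recovery models.

For k coded factors X_1..X_k the recovery response is modelled as

    Y = b0 + sum_i b_i X_i + sum_{i<j} b_ij X_i X_j
           + sum_{i<j<k} b_ijk X_i X_j X_k + sum_i b_ii X_i^2

— a second-order model augmented with all three-way interactions. For five
factors this gives 1 + 5 + 10 + 10 + 5 = 31 terms. The term order is fixed
(intercept, linear, two-way, three-way, quadratic; combinations in
lexicographic factor order) and identical across fitting, printing and the
shipped coefficient fixtures.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["n_terms", "term_names", "term_indices", "expand_terms", "TermExpander"]


def n_terms(k: int) -> int:
    """Number of basis terms for k factors: 1 + k + C(k,2) + C(k,3) + k."""
    from math import comb

    return 1 + k + comb(k, 2) + comb(k, 3) + k


def term_indices(k: int) -> list[tuple[int, ...]]:
    """Factor-index tuples per term, in the fixed basis order.

    The intercept is the empty tuple; a quadratic term repeats its index.
    """
    out: list[tuple[int, ...]] = [()]
    out += [(i,) for i in range(k)]
    out += list(itertools.combinations(range(k), 2))
    out += list(itertools.combinations(range(k), 3))
    out += [(i, i) for i in range(k)]
    return out


def term_names(factor_names: Sequence[str]) -> list[str]:
    """Printable labels: b0, b_SW, ..., b_SW-AM, ..., b_SW-SW, ..."""
    names = []
    for idx in term_indices(len(factor_names)):
        if not idx:
            names.append("b0")
        else:
            names.append("b_" + "-".join(factor_names[i] for i in idx))
    return names


def expand_terms(coded: np.ndarray) -> np.ndarray:
    """Expand coded points into the polynomial feature basis.

    Parameters
    ----------
    coded
        A length-k vector or an (n, k) array of coded points.

    Returns
    -------
    numpy.ndarray
        Length-``n_terms(k)`` vector, or (n, n_terms(k)) matrix, with the
        intercept feature identically 1.
    """
    coded = np.asarray(coded, dtype=float)
    single = coded.ndim == 1
    X = np.atleast_2d(coded)
    k = X.shape[1]
    cols = [np.ones(X.shape[0])]
    for idx in term_indices(k)[1:]:
        col = X[:, idx[0]].copy()
        for i in idx[1:]:
            col *= X[:, i]
        cols.append(col)
    features = np.column_stack(cols)
    return features[0] if single else features


class TermExpander(TransformerMixin, BaseEstimator):
    """Transformer expanding coded factors into the polynomial basis.

    Stateless apart from recording the number of factors seen during
    ``fit``; composes with scikit-learn pipelines.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D array of coded points")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X must have shape (n, {self.n_features_in_})"
            )
        return expand_terms(X)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        if input_features is None:
            input_features = [f"x{i}" for i in range(self.n_features_in_)]
        return np.asarray(term_names(list(input_features)), dtype=object)
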