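"""Round-level feature conditioning.

Before clustering, the pooled image-feature matrix for a round is column
centered (zero mean, unit standard deviation; population convention, divide by
N) and a linearly independent subset of columns is selected by a greedy
Gram–Schmidt pass.  Zero-variance columns are dropped before scaling.  The
fitted transform is retained so held-out images can be projected into exactly
the feature space a given round's model saw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegenerateInputError",
    "Standardizer",
    "standardize",
    "gram_schmidt_select",
    "FeatureTransform",
    "fit_feature_transform",
]


class DegenerateInputError(ValueError):
    """Raised when the input has too few rows to be standardized."""


@dataclass
class Standardizer:
    """Column centering/scaling fitted on one round's pooled features.

    ``kept`` are the indices of columns with nonzero variance; ``dropped``
    the flagged constant columns.  Standard deviation uses the population
    convention (ddof=0).
    """

    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray
    dropped: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X[:, self.kept] - self.mean) / self.sd


def _fit_standardizer(X: np.ndarray) -> Standardizer:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if X.shape[0] < 2:
        raise DegenerateInputError("standardization needs at least 2 rows")
    if not np.isfinite(X).all():
        raise ValueError("matrix contains missing or non-finite values")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    # a column is constant if its spread is negligible relative to its location
    tol = 1e-12 * np.maximum(1.0, np.abs(mean))
    kept = np.flatnonzero(sd > tol)
    dropped = np.flatnonzero(sd <= tol)
    return Standardizer(mean=mean[kept], sd=sd[kept], kept=kept, dropped=dropped)


def standardize(X: np.ndarray) -> tuple[np.ndarray, Standardizer]:
    """Center to zero mean and scale to unit (population) SD per column.

    Zero-variance columns are dropped and reported via the returned
    :class:`Standardizer`.  Returns ``(transformed, standardizer)``.
    """
    st = _fit_standardizer(X)
    return st.transform(np.asarray(X, dtype=float)), st


def gram_schmidt_select(X: np.ndarray, tol: float = 1e-8) -> list[int]:
    """Greedy left-to-right selection of a linearly independent column subset.

    A column is retained iff the norm of its residual, after projection onto
    the span of previously retained columns, exceeds ``tol`` times its own
    norm.  The input is expected to be standardized.  Returns the ordered
    retained column indices; the retained set spans all columns within tol.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    n, d = X.shape
    Q = np.empty((n, 0))
    selected: list[int] = []
    for j in range(d):
        x = X[:, j]
        norm0 = np.linalg.norm(x)
        if norm0 == 0.0:
            continue
        # two projection passes for numerical stability (re-orthogonalization)
        r = x - Q @ (Q.T @ x)
        r = r - Q @ (Q.T @ r)
        rnorm = np.linalg.norm(r)
        if rnorm > tol * norm0:
            selected.append(j)
            Q = np.column_stack([Q, r / rnorm])
    return selected


@dataclass
class FeatureTransform:
    """Composite round transform: standardize then keep Gram–Schmidt columns."""

    standardizer: Standardizer
    selected: list[int] = field(default_factory=list)

    def apply(self, X: np.ndarray) -> np.ndarray:
        return self.standardizer.transform(X)[:, self.selected]


def fit_feature_transform(X: np.ndarray, tol: float = 1e-8) -> tuple[np.ndarray, FeatureTransform]:
    """Fit the full round-level conditioning on pooled features.

    Returns the conditioned matrix and the reusable transform.
    """
    Xs, st = standardize(X)
    selected = gram_schmidt_select(Xs, tol=tol)
    return Xs[:, selected], FeatureTransform(standardizer=st, selected=selected)
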