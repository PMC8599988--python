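"""Empirical feasibility boundary between effective contact and flight time.

The crossing equation has no solution with non-negative flight time when
t_fe falls below ~0.784 * t_ce.  On a discrete grid this shows up as a sharp
edge: for every t_ce axis value there is a smallest t_fe with a solution.
Those edge points are extracted and summarized by a straight line through
the origin (a zero t_ce forces a zero t_fe), fitted by ordinary least
squares on a random 85% training subset and scored on the held-out 15%.

The fitted slope slightly exceeds the closed-form existence ratio because
each extracted boundary point overshoots the true line by up to one grid
spacing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from ._split import DEFAULT_SEED, DEFAULT_TRAIN_FRACTION, split_indices
from .solver import GridSolution

__all__ = ["BoundaryLine", "BoundaryFit", "extract_boundary_points", "fit_boundary"]


class EmptyBoundaryError(ValueError):
    """Raised when a grid contains no solved points to extract a boundary from."""


class BoundaryLine(RegressorMixin, BaseEstimator):
    """Through-origin least-squares line ``y = slope * x``.

    scikit-learn estimator over a single feature; the y-intercept is pinned
    to zero.  The fitted slope is ``sum(x*y) / sum(x^2)``.

    Attributes
    ----------
    slope_ : float
        Fitted slope.
    """

    def fit(self, X, y):
        X, y = validate_data(self, X, y, ensure_min_samples=2)
        if X.shape[1] != 1:
            raise ValueError("BoundaryLine expects a single feature column")
        x = X[:, 0]
        denom = float(x @ x)
        if denom == 0.0:
            raise ValueError("all x values are zero; slope undefined")
        self.slope_ = float(x @ y) / denom
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.slope_ * X[:, 0]

    def score(self, X, y):
        """Uncentered R^2, the baseline consistent with a no-intercept model."""
        check_is_fitted(self)
        y = np.asarray(y, dtype=float)
        resid = y - self.predict(X)
        total = float(y @ y)
        if total == 0.0:
            raise ValueError("cannot score on all-zero targets")
        return 1.0 - float(resid @ resid) / total


@dataclass
class BoundaryFit:
    """Result of fitting the boundary line on a random train/test split."""

    slope: float
    r_squared: float
    rmse: float  # seconds, on the held-out test points
    train_idx: np.ndarray = field(repr=False)
    test_idx: np.ndarray = field(repr=False)
    seed: int = DEFAULT_SEED
    n_points: int = 0

    def to_json(self, path=None) -> str:
        doc = json.dumps(
            {
                "schema": 1,
                "slope": self.slope,
                "r_squared": self.r_squared,
                "rmse_ms": self.rmse * 1e3,
                "n_points": self.n_points,
                "seed": self.seed,
                "train_idx": self.train_idx.tolist(),
                "test_idx": self.test_idx.tolist(),
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc)
        return doc


def extract_boundary_points(grid: GridSolution) -> np.ndarray:
    """Smallest solvable t_fe for every t_ce axis value, as an (k, 2) array.

    With the default grid every one of the 68 t_ce values has a solvable
    t_fe, so k = 68.
    """
    mask = grid.solved_mask
    points = []
    for i, tce in enumerate(grid.t_ce_values):
        js = np.flatnonzero(mask[i])
        if js.size:
            points.append((tce, grid.t_fe_values[js[0]]))
    if not points:
        raise EmptyBoundaryError("grid contains no solved points")
    return np.asarray(points)


def fit_boundary(
    points: np.ndarray,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = DEFAULT_SEED,
) -> BoundaryFit:
    """Fit the through-origin boundary line on a random split of the points.

    RMSE and (uncentered) R^2 are computed on the held-out test points.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or len(points) < 2:
        raise ValueError("need an (n, 2) array with n >= 2 boundary points")
    train, test = split_indices(len(points), train_fraction, seed)
    X, y = points[:, :1], points[:, 1]
    line = BoundaryLine().fit(X[train], y[train])
    resid = y[test] - line.predict(X[test])
    return BoundaryFit(
        slope=line.slope_,
        r_squared=line.score(X[test], y[test]),
        rmse=float(np.sqrt(np.mean(resid**2))),
        train_idx=train,
        test_idx=test,
        seed=seed,
        n_points=len(points),
    )
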