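"""Numerical solution of the body-weight-crossing time t_g.

The residual (:func:`stridetime.model.eq1_residual`) decreases from +inf at
t_g -> 0+, reaches a minimum, and increases again; the physically meaningful
root is the smallest one, lying between 0 and the residual minimum.  Flight
time must stay non-negative, which caps the search at t_g = t_fe / 2.  The
bracket is located with a bounded derivative-free scalar minimizer, then the
root is polished with Brent's method.  If the bracketed minimum stays
positive the pair is infeasible and NaN is returned as the no-solution
marker — infeasible pairs are a legitimate part of the grid, not an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .model import TimingPair, eq1_residual

__all__ = [
    "NO_SOLUTION",
    "ConvergenceError",
    "GridSpec",
    "GridSolution",
    "solve_tg",
    "solve_grid",
]

#: Value-level marker for pairs with no root with non-negative flight time.
NO_SOLUTION = math.nan

_EPS = 1e-9  # lower bracket on t_g, seconds
_XTOL = 1e-12  # root tolerance on t_g, seconds
_MAXITER = 200
# a bracketed minimum this close to zero is treated as a boundary tangency
# (root at the minimizer) rather than evidence of infeasibility
_TANGENCY_TOL = 1e-9


class ConvergenceError(RuntimeError):
    """Root-finding failed to converge (distinct from a no-solution pair)."""


@dataclass(frozen=True)
class GridSpec:
    """Square grid of (t_ce, t_fe) values, seconds.

    The defaults span 2.5–505 ms in 7.5 ms steps, 68 values per axis
    (4,624 points), covering the physiological range of running step timings
    with generous margins.
    """

    start: float = 0.0025
    stop: float = 0.505
    spacing: float = 0.0075

    def __post_init__(self) -> None:
        if not (self.start > 0):
            raise ValueError("start must be positive")
        if not (self.spacing > 0):
            raise ValueError("spacing must be positive")
        if self.stop < self.start:
            raise ValueError("stop must be >= start")

    @property
    def n_axis(self) -> int:
        # integer-index formula; the small slack absorbs floating-point drift
        return int(math.floor((self.stop - self.start) / self.spacing + 1e-9)) + 1

    def axis(self) -> np.ndarray:
        """Axis values start + i*spacing, identical for both axes."""
        return self.start + self.spacing * np.arange(self.n_axis)


@dataclass
class GridSolution:
    """Solved t_g over the t_ce x t_fe grid; NaN marks unsolved points.

    ``t_g[i, j]`` corresponds to ``t_ce_values[i]``, ``t_fe_values[j]``.
    """

    t_ce_values: np.ndarray
    t_fe_values: np.ndarray
    t_g: np.ndarray
    spec: GridSpec | None = None
    tolerance: float = field(default=1e-4)

    @property
    def n_total(self) -> int:
        return int(self.t_g.size)

    @property
    def n_solved(self) -> int:
        return int(np.isfinite(self.t_g).sum())

    @property
    def n_unsolved(self) -> int:
        return self.n_total - self.n_solved

    @property
    def solved_mask(self) -> np.ndarray:
        return np.isfinite(self.t_g)

    def solved_points(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, y): solved (t_ce, t_fe) pairs as an (n, 2) array and their t_g."""
        mask = self.solved_mask
        tce, tfe = np.meshgrid(self.t_ce_values, self.t_fe_values, indexing="ij")
        X = np.column_stack([tce[mask], tfe[mask]])
        return X, self.t_g[mask]

    def to_frame(self) -> pd.DataFrame:
        """Long format, milliseconds: tce_ms, tfe_ms, tg_ms (NaN if unsolved)."""
        tce, tfe = np.meshgrid(self.t_ce_values, self.t_fe_values, indexing="ij")
        return pd.DataFrame(
            {
                "tce_ms": tce.ravel() * 1e3,
                "tfe_ms": tfe.ravel() * 1e3,
                "tg_ms": self.t_g.ravel() * 1e3,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GridSolution":
        df = pd.read_csv(path)
        for col in ("tce_ms", "tfe_ms", "tg_ms"):
            if col not in df.columns:
                raise ValueError(f"grid CSV missing column {col!r}")
        tce = np.unique(df["tce_ms"].to_numpy()) * 1e-3
        tfe = np.unique(df["tfe_ms"].to_numpy()) * 1e-3
        if len(df) != len(tce) * len(tfe):
            raise ValueError("grid CSV is not a complete rectangular grid")
        order = np.lexsort((df["tfe_ms"].to_numpy(), df["tce_ms"].to_numpy()))
        tg = df["tg_ms"].to_numpy()[order].reshape(len(tce), len(tfe)) * 1e-3
        return cls(t_ce_values=tce, t_fe_values=tfe, t_g=tg)


def solve_tg(
    pair: TimingPair,
    tolerance: float = 1e-4,
    *,
    eps: float = _EPS,
    xtol: float = _XTOL,
    maxiter: int = _MAXITER,
) -> float:
    """Smallest root t_g of the crossing equation, or NaN if none exists.

    The search interval is (eps, t_fe/2]: the upper cap enforces a
    non-negative flight time.  Contract: the bracketed residual minimum is
    located first; a positive minimum means no solution.  A returned root
    is accurate to ``xtol`` in t_g and satisfies
    ``|eq1_residual(t_g, pair)| <= tolerance`` (the residual slope can reach
    ~1e6 s^-1 near the small-t_ce corner, so the residual check is a sanity
    bound, not the convergence criterion) and ``0 < t_g <= t_fe/2``.
    """
    hi = pair.t_fe / 2.0
    if hi <= eps:
        return NO_SOLUTION

    def f(tg: float) -> float:
        return eq1_residual(tg, pair)

    if f(hi) <= 0.0:
        # the residual already crosses zero by the zero-flight-time cap
        # (t_fe = 0.7836.. t_ce sits exactly here); bracket is [eps, hi]
        upper = hi
    else:
        res = minimize_scalar(
            f, bounds=(eps, hi), method="bounded", options={"xatol": xtol, "maxiter": maxiter}
        )
        fmin = float(res.fun)
        if fmin > _TANGENCY_TOL:
            return NO_SOLUTION
        if fmin > 0.0:
            # tangency at the feasibility boundary: the minimum grazes zero
            return float(res.x)
        upper = float(res.x)
    if f(eps) <= 0.0:  # pragma: no cover - eps is deep in the divergent region
        raise ConvergenceError("lower bracket does not enclose the root")
    root, info = brentq(f, eps, upper, xtol=xtol, maxiter=maxiter, full_output=True, disp=False)
    if not info.converged:
        raise ConvergenceError(
            f"Brent iteration did not converge for pair {pair!r} within {maxiter} iterations"
        )
    root = float(root)
    if abs(f(root)) > tolerance:
        raise ConvergenceError(
            f"root residual {f(root):.3e} exceeds tolerance {tolerance:.3e} for {pair!r}"
        )
    return root


def solve_grid(spec: GridSpec | None = None, tolerance: float = 1e-4) -> GridSolution:
    """Solve the crossing equation at every grid point.

    With the default spec this yields 4,624 points of which 1,814 admit no
    solution with non-negative flight time (they lie below the feasibility
    boundary t_fe ~ 0.784 t_ce).
    """
    if spec is None:
        spec = GridSpec()
    axis = spec.axis()
    tg = np.full((len(axis), len(axis)), np.nan)
    for i, tce in enumerate(axis):
        for j, tfe in enumerate(axis):
            try:
                tg[i, j] = solve_tg(TimingPair(tce, tfe), tolerance)
            except ConvergenceError as exc:  # pragma: no cover - defensive
                raise ConvergenceError(
                    f"grid point (t_ce={tce:.6f}, t_fe={tfe:.6f}) failed: {exc}"
                ) from exc
    return GridSolution(
        t_ce_values=axis, t_fe_values=axis.copy(), t_g=tg, spec=spec, tolerance=tolerance
    )
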