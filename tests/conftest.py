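import numpy as np
import pytest

from stridetime import GridSpec, TimingPair, solve_grid, solve_tg
from stridetime.model import eq1_residual


@pytest.fixture(scope="session")
def default_grid():
    """The default 68x68 grid, solved once per test session."""
    return solve_grid(GridSpec())


def bisection_oracle(t_ce: float, t_fe: float, iters: int = 80) -> float:
    """Independent root finder: linear scan for the first sign change of the
    residual over (0, t_fe/2], then plain bisection.  Deliberately naive."""
    pair = TimingPair(t_ce, t_fe)
    grid = np.linspace(1e-6, t_fe / 2, 20001)
    lo = hi = None
    prev_t, prev_v = grid[0], eq1_residual(grid[0], pair)
    for t in grid[1:]:
        v = eq1_residual(t, pair)
        if prev_v > 0 >= v:
            lo, hi = prev_t, t
            break
        prev_t, prev_v = t, v
    if lo is None:
        return float("nan")
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if eq1_residual(mid, pair) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@pytest.fixture(scope="session")
def oracle():
    return bisection_oracle


@pytest.fixture(scope="session")
def random_feasible_pairs():
    """100 random pairs above the feasibility boundary, seconds."""
    rng = np.random.default_rng(1234)
    pairs = []
    while len(pairs) < 100:
        t_ce = rng.uniform(0.05, 0.45)
        t_fe = rng.uniform(0.8 * t_ce, 0.45)
        if np.isfinite(solve_tg(TimingPair(t_ce, t_fe))):
            pairs.append(TimingPair(t_ce, t_fe))
    return pairs
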