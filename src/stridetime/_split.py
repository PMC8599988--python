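"""Shared train/test split convention: uniform random, round(frac*n) training points."""

from __future__ import annotations

import numpy as np

DEFAULT_SEED = 42
DEFAULT_TRAIN_FRACTION = 0.85


def split_indices(
    n: int, train_fraction: float = DEFAULT_TRAIN_FRACTION, seed: int = DEFAULT_SEED
) -> tuple[np.ndarray, np.ndarray]:
    """Random (train, test) index arrays with round(train_fraction*n) training points."""
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must lie in (0, 1)")
    if n < 2:
        raise ValueError("need at least 2 points to split")
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    return perm[:n_train], perm[n_train:]
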