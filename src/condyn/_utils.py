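"""Shared helpers: seeding and validation."""

from __future__ import annotations

import numpy as np


def rng_from(seed: int, *stream: int) -> np.random.Generator:
    """PCG64 generator for a named sub-stream of a master seed.

    All randomness in the package flows through this function so that a
    single integer seed reproduces every artifact bit-identically.  Each
    distinct ``stream`` tuple (e.g. ``(stage_id, block)``) yields an
    independent child of ``SeedSequence(seed)``.
    """
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(s) for s in stream)))


def check_stochastic(matrix: np.ndarray, atol: float = 1e-12) -> np.ndarray:
    """Validate a row-stochastic matrix; returns it as float64.

    Raises ValueError naming the first offending row.
    """
    T = np.asarray(matrix, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError(f"transition matrix must be square, got shape {T.shape}")
    if np.any(T < 0):
        i, j = np.argwhere(T < 0)[0]
        raise ValueError(f"transition matrix has negative entry at ({i}, {j}): {T[i, j]}")
    rowsums = T.sum(axis=1)
    bad = np.where(np.abs(rowsums - 1.0) > atol)[0]
    if bad.size:
        i = int(bad[0])
        raise ValueError(f"row {i} of transition matrix sums to {rowsums[i]!r}, not 1 (tolerance {atol})")
    return T


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary distribution from the leading left eigenvector."""
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmax(vals.real))
    pi = np.abs(vecs[:, i].real)
    return pi / pi.sum()
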