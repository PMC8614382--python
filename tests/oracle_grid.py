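"""Brute-force simplex grid-search oracle for small envelopment problems.

Independent of the LP path: the radial score and the phase-2 slack
objective are maximized by exhaustive search over intensity vectors on a
discrete simplex grid. An optimal basic solution of the radial LP has at
most m+1 positive intensities (one output row plus the convexity row and
m input rows), so enumerating supports of size <= m+1 with a step-h grid
on each support simplex visits a grid neighbourhood of every vertex
solution. Intended for n <= 6, m <= 2.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

import numpy as np


@lru_cache(maxsize=None)
def _compositions(d: int, total: int) -> np.ndarray:
    """All ways to write `total` as an ordered sum of d nonnegative ints."""
    if d == 1:
        return np.array([[total]], dtype=np.int32)
    rows = []
    for first in range(total + 1):
        rest = _compositions(d - 1, total - first)
        block = np.empty((rest.shape[0], d), dtype=np.int32)
        block[:, 0] = first
        block[:, 1:] = rest
        rows.append(block)
    return np.vstack(rows)


def _simplex_grid(d: int, steps: int) -> np.ndarray:
    """All weight vectors of length d on the simplex with entries k/steps."""
    return _compositions(d, steps) / float(steps)


def grid_theta(X: np.ndarray, y: np.ndarray, i: int, step: float = 0.005) -> float:
    """Best radial output expansion found on the grid (a lower bound on the
    true optimum; within a grid-resolution band of it)."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n, m = y.size, X.shape[0]
    steps = int(round(1.0 / step))
    best = 1.0  # the DMU itself is always feasible
    max_support = min(n, m + 1)
    for size in range(1, max_support + 1):
        W = _simplex_grid(size, steps)
        for supp in combinations(range(n), size):
            idx = list(supp)
            agg_in = W @ X[:, idx].T          # (K, m)
            feasible = np.all(agg_in <= X[:, i] + 1e-12, axis=1)
            if not feasible.any():
                continue
            out = W @ y[idx]
            best = max(best, float(out[feasible].max()) / y[i])
    return best


def brute_force_slacks(
    X: np.ndarray,
    y: np.ndarray,
    i: int,
    theta: float,
    weights_in: np.ndarray | None = None,
    weight_out: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Exact slack-phase optimum by enumerating basic feasible solutions.

    At the fixed radial score the feasible set is a (possibly
    degenerate) face, so a simplex grid over intensities rarely touches
    it; instead every basic solution of the equality system

        [y  0 -1] [lambda]   [theta*y_i]
        [X  I  0] [s     ] = [x_i      ]
        [1  0  0] [s_out ]   [1        ]

    (m+2 rows, n+m+1 columns) is enumerated directly: choose m+2 columns,
    solve the square system, keep nonnegative solutions, and return the
    slack vector with maximal weighted total. The optimum of a bounded LP
    is attained at such a basic solution, so this is exact up to linear
    algebra roundoff.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n, m = y.size, X.shape[0]
    if weights_in is None:
        weights_in = np.ones(m)
    nv = n + m + 1
    A = np.zeros((m + 2, nv))
    A[0, :n] = y
    A[0, n + m] = -1.0
    A[1 : 1 + m, :n] = X
    A[1 : 1 + m, n : n + m] = np.eye(m)
    A[m + 1, :n] = 1.0
    b = np.concatenate([[theta * y[i]], X[:, i], [1.0]])
    cost = np.concatenate([np.zeros(n), weights_in, [weight_out]])
    best_val = -np.inf
    best = (np.zeros(m), 0.0)
    for cols in combinations(range(nv), m + 2):
        B = A[:, cols]
        try:
            zb = np.linalg.solve(B, b)
        except np.linalg.LinAlgError:
            continue
        if not np.all(np.isfinite(zb)) or np.any(zb < -1e-8):
            continue
        z = np.zeros(nv)
        z[list(cols)] = zb
        val = float(cost @ z)
        if val > best_val:
            best_val = val
            best = (np.maximum(z[n : n + m], 0.0), max(float(z[n + m]), 0.0))
    if best_val == -np.inf:
        raise RuntimeError("no basic feasible solution found at the given theta")
    return best


def random_instance(rng: np.random.Generator, n_max: int = 6, m_max: int = 2):
    """A small random envelopment instance (X m-by-n, y length n)."""
    n = int(rng.integers(2, n_max + 1))
    m = int(rng.integers(1, m_max + 1))
    X = rng.uniform(0.5, 5.0, size=(m, n))
    y = rng.uniform(1.0, 10.0, size=n)
    return X, y
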