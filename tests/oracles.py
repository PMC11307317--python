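"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they validate: the LP oracle
enumerates basic feasible solutions instead of calling a solver, and the
segmentation oracle brute-forces breakpoints with numpy.polyfit.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_vertices(S: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> np.ndarray:
    """All vertices of {v : S v = 0, lb <= v <= ub} by basis enumeration.

    A vertex has at least n - rank(S) coordinates at a bound; enumerate every
    choice of free coordinates and bound assignment, solve the equality
    system for the free part, and keep feasible solutions.  Exponential —
    intended for networks with <= ~8 reactions.
    """
    m, n = S.shape
    r = np.linalg.matrix_rank(S)
    n_free = r
    vertices = []
    for free in itertools.combinations(range(n), n_free):
        fixed = [j for j in range(n) if j not in free]
        S_f = S[:, list(free)]
        for bounds_choice in itertools.product(*([(lb[j], ub[j]) for j in fixed] or [()])):
            v = np.zeros(n)
            for j, val in zip(fixed, bounds_choice):
                v[j] = val
            rhs = -S[:, fixed] @ v[fixed] if fixed else np.zeros(m)
            sol, residual, rank, _ = np.linalg.lstsq(S_f, rhs, rcond=None)
            v[list(free)] = sol
            if np.max(np.abs(S @ v)) > 1e-8:
                continue
            if np.all(v >= lb - 1e-9) and np.all(v <= ub + 1e-9):
                vertices.append(np.clip(v, lb, ub))
    if not vertices:
        return np.empty((0, n))
    return np.unique(np.round(np.array(vertices), 9), axis=0)


def lp_optimum_by_enumeration(S, lb, ub, c) -> float | None:
    """max c^T v over the flux polytope via vertex enumeration (None if empty)."""
    verts = enumerate_vertices(np.asarray(S, float), np.asarray(lb, float), np.asarray(ub, float))
    if verts.shape[0] == 0:
        return None
    return float(np.max(verts @ np.asarray(c, float)))


def random_bounded_network(rng: np.random.Generator, max_rxns: int = 8):
    """A random small stoichiometric network with finite bounds."""
    n = int(rng.integers(3, max_rxns + 1))
    m = int(rng.integers(1, max(2, n - 1)))
    S = rng.integers(-2, 3, size=(m, n)).astype(float)
    # ensure no empty reactions
    for j in range(n):
        if not np.any(S[:, j]):
            S[rng.integers(0, m), j] = 1.0
    lb = rng.uniform(-10, 0, size=n)
    ub = lb + rng.uniform(0.5, 10, size=n)
    c = rng.uniform(-1, 1, size=n)
    return S, lb, ub, c


def brute_force_segmentation(x: np.ndarray, y: np.ndarray, k: int, min_seg: int = 2):
    """Optimal k-segment piecewise-linear SSE by exhaustive breakpoint search."""
    n = len(x)
    best = np.inf
    best_breaks: tuple = ()

    def seg_sse(a, b):
        if b - a < 2:
            return 0.0
        coef = np.polyfit(x[a:b], y[a:b], 1)
        return float(np.sum((y[a:b] - np.polyval(coef, x[a:b])) ** 2))

    for breaks in itertools.combinations(range(min_seg, n - min_seg + 1), k - 1):
        bounds = (0, *breaks, n)
        if any(b - a < min_seg for a, b in zip(bounds[:-1], bounds[1:])):
            continue
        sse = sum(seg_sse(a, b) for a, b in zip(bounds[:-1], bounds[1:]))
        if sse < best - 1e-12:
            best, best_breaks = sse, breaks
    return best, list(best_breaks)
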