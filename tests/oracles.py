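"""Independent brute-force oracles used only by the test suite.

These deliberately use naive algorithms (explicit double loops, path
enumeration, exhaustive KKT-candidate search) so they share no code
path with the implementation they check.
"""

from __future__ import annotations

import cmath
import itertools
import math

import numpy as np


def naive_plv(phases_u: np.ndarray, phases_v: np.ndarray, center: int, w_l: int) -> float:
    """Direct double-loop evaluation of the across-trial PLV at one latency."""
    n_samples, n_trials = phases_u.shape
    half = w_l // 2
    acc = 0.0 + 0.0j
    for k in range(n_trials):
        inner = 0.0 + 0.0j
        for n in range(center - half, center + half + 1):
            inner += cmath.exp(1j * (phases_u[n, k] - phases_v[n, k]))
        acc += inner / w_l
    return abs(acc) / n_trials


def naive_pli(phases_u: np.ndarray, phases_v: np.ndarray, center: int, w_l: int) -> float:
    """Direct double-loop PLI: outer absolute value around the full sum."""
    n_samples, n_trials = phases_u.shape
    half = w_l // 2
    acc = 0.0
    for k in range(n_trials):
        for n in range(center - half, center + half + 1):
            acc += np.sign(math.sin(phases_u[n, k] - phases_v[n, k]))
    return abs(acc) / (n_trials * w_l)


def _shortest_path_enum(lengths: np.ndarray, src: int, dst: int) -> float:
    """Shortest path by exhaustive enumeration of simple paths (tiny graphs)."""
    n = lengths.shape[0]
    others = [i for i in range(n) if i not in (src, dst)]
    best = math.inf
    for r in range(len(others) + 1):
        for mid in itertools.permutations(others, r):
            path = (src, *mid, dst)
            total = 0.0
            ok = True
            for a, b in zip(path[:-1], path[1:]):
                if lengths[a, b] == 0 or not math.isfinite(lengths[a, b]):
                    ok = False
                    break
                total += lengths[a, b]
            if ok:
                best = min(best, total)
    return best


def exhaustive_local_efficiency(W: np.ndarray) -> float:
    """Weighted local efficiency by brute-force path enumeration (N ≤ ~7)."""
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        sub = W[np.ix_(nbrs, nbrs)]
        lengths = np.where(sub > 0, 1.0 / np.where(sub > 0, sub, 1.0), 0.0)
        acc = 0.0
        for a, b in itertools.permutations(range(k), 2):
            d = _shortest_path_enum(lengths, a, b)
            if math.isfinite(d) and d > 0:
                acc += 1.0 / d
        total += acc / (k * (k - 1))
    return total / n


def exact_dominant_support(W: np.ndarray, tol: float = 1e-9) -> frozenset:
    """Support of the global maximizer of y'Wy over the simplex.

    Enumerates the KKT candidate of every face (support subset): on a
    face with support S the interior critical point solves W_S x = c·1
    with x > 0; feasibility additionally requires (W y)_i ≤ F off S.
    The global maximum is attained at one of these candidates (vertices
    give F = 0 since the diagonal is zero).
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    best_f, best_y = 0.0, None
    for r in range(2, n + 1):
        for S in itertools.combinations(range(n), r):
            Ws = W[np.ix_(S, S)]
            try:
                x = np.linalg.solve(Ws, np.ones(r))
            except np.linalg.LinAlgError:
                continue
            if np.any(x <= 0):
                continue
            y = x / x.sum()
            f = float(y @ Ws @ y)
            y_full = np.zeros(n)
            y_full[list(S)] = y
            if np.any(W @ y_full > f + tol):
                continue
            if f > best_f:
                best_f, best_y = f, y_full
    if best_y is None:
        return frozenset()
    return frozenset(int(i) for i in np.flatnonzero(best_y > tol))


def planted_clique_graph(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random weighted graph with a well-separated dominant clique."""
    k = int(rng.integers(2, n))
    clique = rng.choice(n, size=k, replace=False)
    W = np.triu(rng.uniform(0.05, 0.4, (n, n)), 1)
    for i, j in itertools.combinations(sorted(int(c) for c in clique), 2):
        W[i, j] = rng.uniform(0.7, 1.0)
    np.fill_diagonal(W, 0.0)
    return W + W.T
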