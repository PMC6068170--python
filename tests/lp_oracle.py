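"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and libraries) they verify:
the LP oracle enumerates vertices of the flux polytope directly, and the
rank-sum oracle enumerates label assignments with plain Python.
"""

from __future__ import annotations

import itertools

import numpy as np


def flux_polytope_maximum(S, lb, ub, objective_index) -> float | None:
    """Maximum of v[objective_index] over {v : S·v = 0, lb ≤ v ≤ ub}.

    Exhaustive vertex enumeration: every vertex of the polytope is a
    basic solution with at least n − rank(S) flux bounds active.  Only
    practical for tiny networks (n ≤ ~6).  Returns None when the
    polytope is empty.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S)
    n_active = n - rank
    best = None
    tol = 1e-9
    for active in itertools.combinations(range(n), n_active):
        free = [i for i in range(n) if i not in active]
        for choices in itertools.product(*[(lb[i], ub[i]) for i in active]):
            v = np.empty(n)
            for i, val in zip(active, choices):
                v[i] = val
            if free:
                A = S[:, free]
                b = -S[:, list(active)] @ np.array(choices)
                x, *_ = np.linalg.lstsq(A, b, rcond=None)
                if np.linalg.norm(A @ x - b) > tol:
                    continue  # inconsistent basis
                for i, val in zip(free, x):
                    v[i] = val
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            if np.linalg.norm(S @ v) > tol:
                continue
            value = v[objective_index]
            if best is None or value > best:
                best = value
    return best


def ranksum_exact_p(group1, group2) -> float:
    """Exact two-sided rank-sum p by full enumeration (midranks,
    doubled one-sided tail capped at 1)."""
    x = list(map(float, group1))
    y = list(map(float, group2))
    pooled = x + y
    n, n1 = len(pooled), len(x)
    # midranks without scipy
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    w_obs = sum(ranks[:n1])
    total = lower = upper = 0
    eps = 1e-9
    for combo in itertools.combinations(range(n), n1):
        w = sum(ranks[i] for i in combo)
        total += 1
        if w <= w_obs + eps:
            lower += 1
        if w >= w_obs - eps:
            upper += 1
    return min(1.0, 2.0 * min(lower / total, upper / total))
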