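"""Independent naive oracles, coded with explicit loops.

These deliberately avoid the package's vectorized code paths (and
numpy where feasible) so agreement with the implementation is a real
cross-check, not a tautology.
"""

from __future__ import annotations

import numpy as np


def brute_cosine_matrix(values) -> np.ndarray:
    """Double-loop cosine similarity of a binary profile, diagonal forced to 1."""
    values = [list(map(float, row)) for row in values]
    n = len(values)
    norms = [sum(a * a for a in row) ** 0.5 for row in values]
    S = [[0.0] * n for _ in range(n)]
    for i in range(n):
        S[i][i] = 1.0
        for j in range(i + 1, n):
            dot = sum(a * b for a, b in zip(values[i], values[j]))
            s = dot / (norms[i] * norms[j]) if norms[i] > 0 and norms[j] > 0 else 0.0
            S[i][j] = S[j][i] = s
    return np.array(S)


def naive_full_kernel(W) -> list[list[float]]:
    n = len(W)
    P = [[0.0] * n for _ in range(n)]
    for i in range(n):
        mass = sum(W[i][k] for k in range(n) if k != i)
        if mass == 0:
            P[i][i] = 1.0
        else:
            for j in range(n):
                P[i][j] = 0.5 if j == i else W[i][j] / (2.0 * mass)
    return P


def naive_knn(W, K) -> list[list[float]]:
    n = len(W)
    S = [[0.0] * n for _ in range(n)]
    for i in range(n):
        neighbours = sorted(
            (j for j in range(n) if j != i), key=lambda j: (-W[i][j], j)
        )[:K]
        mass = sum(W[i][j] for j in neighbours)
        if mass > 0:
            for j in neighbours:
                S[i][j] = W[i][j] / mass
    return S


def naive_snf(views, K, T, renormalize=True) -> np.ndarray:
    """Loop-based cross-diffusion over >= 2 views."""
    views = [[list(map(float, row)) for row in v] for v in views]
    n = len(views[0])
    nv = len(views)
    P = [naive_full_kernel(v) for v in views]
    S = [naive_knn(v, K) for v in views]
    for _ in range(T):
        P_new = []
        for v in range(nv):
            M = [
                [
                    sum(P[u][i][j] for u in range(nv) if u != v) / (nv - 1)
                    for j in range(n)
                ]
                for i in range(n)
            ]
            SM = [
                [sum(S[v][i][k] * M[k][j] for k in range(n)) for j in range(n)]
                for i in range(n)
            ]
            Q = [
                [sum(SM[i][k] * S[v][j][k] for k in range(n)) for j in range(n)]
                for i in range(n)
            ]
            Q = [[(Q[i][j] + Q[j][i]) / 2.0 for j in range(n)] for i in range(n)]
            if renormalize:
                Q = naive_full_kernel(Q)
            P_new.append(Q)
        P = P_new
    F = [
        [sum(P[v][i][j] for v in range(nv)) / nv for j in range(n)]
        for i in range(n)
    ]
    return np.array([[(F[i][j] + F[j][i]) / 2.0 for j in range(n)] for i in range(n)])


def mann_whitney_auroc(labels, scores) -> float:
    """Pair-counting AUROC: fraction of (positive, negative) pairs correctly
    ordered, ties counted half."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def brute_top1_successes(affinity, held_out) -> int:
    """Drugs whose held-out disease wins the (score desc, index asc) ranking."""
    wins = 0
    for d, j_star in held_out.items():
        row = list(affinity[d])
        best = max(range(len(row)), key=lambda j: (row[j], -j))
        if best == j_star:
            wins += 1
    return wins
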