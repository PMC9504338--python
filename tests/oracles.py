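"""Independent oracles used by the tests.

Each routine re-derives a quantity by a method unrelated to the package
implementation it checks: quaternion RMSD vs SVD Kabsch, exhaustive path
enumeration vs Floyd-Warshall, direct passage-time simulation vs the MFPT
linear solve, and brute-force partition search vs Girvan-Newman.
"""

from __future__ import annotations

import itertools

import numpy as np


def quaternion_rmsd(X: np.ndarray, Y: np.ndarray) -> float:
    """Optimal superposition RMSD via the quaternion eigenvalue method."""
    X = X - X.mean(axis=0)
    Y = Y - Y.mean(axis=0)
    R = X.T @ Y
    S = np.array([
        [R[0, 0] + R[1, 1] + R[2, 2], R[1, 2] - R[2, 1], R[2, 0] - R[0, 2], R[0, 1] - R[1, 0]],
        [R[1, 2] - R[2, 1], R[0, 0] - R[1, 1] - R[2, 2], R[0, 1] + R[1, 0], R[0, 2] + R[2, 0]],
        [R[2, 0] - R[0, 2], R[0, 1] + R[1, 0], -R[0, 0] + R[1, 1] - R[2, 2], R[1, 2] + R[2, 1]],
        [R[0, 1] - R[1, 0], R[0, 2] + R[2, 0], R[1, 2] + R[2, 1], -R[0, 0] - R[1, 1] + R[2, 2]],
    ])
    lam = np.linalg.eigvalsh(S)[-1]
    n = X.shape[0]
    msd = max((np.sum(X * X) + np.sum(Y * Y) - 2.0 * lam) / n, 0.0)
    return float(np.sqrt(msd))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation from a normalized quaternion."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def exhaustive_shortest_distance(nodes, edges: dict, a, b) -> float:
    """Minimal total weight over all simple paths a -> b (n <= 8 only)."""
    adj = {u: {} for u in nodes}
    for (u, v), w in edges.items():
        adj[u][v] = w
        adj[v][u] = w
    best = [np.inf]

    def walk(u, seen, cost):
        if cost >= best[0]:
            return
        if u == b:
            best[0] = cost
            return
        for v, w in adj[u].items():
            if v not in seen:
                walk(v, seen | {v}, cost + w)

    walk(a, {a}, 0.0)
    return best[0]


def best_two_partition_modularity(nodes, edges: dict):
    """Max unweighted-modularity split into <= 2 groups, by brute force."""
    nodes = list(nodes)
    n = len(nodes)
    m = len(edges)
    deg = {u: 0 for u in nodes}
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1

    def modularity(groups):
        Q = 0.0
        for g in groups:
            gs = set(g)
            intra = sum(1 for (u, v) in edges if u in gs and v in gs)
            dg = sum(deg[u] for u in g)
            Q += intra / m - (dg / (2 * m)) ** 2
        return Q

    best_q, best_part = modularity([nodes]), [sorted(nodes)]
    for bits in range(1, 2 ** (n - 1)):
        g1 = [nodes[i] for i in range(n) if bits >> i & 1]
        g2 = [u for u in nodes if u not in g1]
        if not g1 or not g2:
            continue
        q = modularity([g1, g2])
        if q > best_q + 1e-12:
            best_q, best_part = q, sorted([sorted(g1), sorted(g2)])
    return best_q, best_part


def simulate_first_passage(T: np.ndarray, start: int, target: int,
                           n_passages: int, rng: np.random.Generator) -> np.ndarray:
    """Direct simulation of first-passage times start -> target (batched)."""
    n = T.shape[0]
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0
    state = np.full(n_passages, start, dtype=np.int64)
    steps = np.zeros(n_passages, dtype=np.int64)
    alive = state != target
    while alive.any():
        u = rng.random(int(alive.sum()))
        s = state[alive]
        nxt = np.empty_like(s)
        for k in range(n):
            mask = s == k
            if mask.any():
                nxt[mask] = np.searchsorted(cum[k], u[mask], side="right")
        state[alive] = nxt
        steps[alive] += 1
        alive = state != target
    return steps


def representative_bruteforce(coords: np.ndarray, rmsd_fn) -> tuple[int, float]:
    """Direct evaluation of the exponential-similarity score for every frame."""
    F = coords.shape[0]
    D = np.zeros((F, F))
    for i in range(F):
        for j in range(F):
            if i != j:
                D[i, j] = rmsd_fn(coords[i], coords[j])
    d_scale = D[np.triu_indices(F, 1)].std(ddof=0)
    scores = np.array([np.mean([np.exp(-D[i, j] / d_scale) for j in range(F) if j != i])
                       for i in range(F)])
    return int(np.argmax(scores)), float(scores.max())
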