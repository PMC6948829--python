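"""Independent brute-force / closed-form oracles used by the tests.

Everything here is deliberately naive (explicit loops, exhaustive
enumeration, closed forms valid only in special cases) and shares no code
with the package implementations it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# Graph metrics
# ---------------------------------------------------------------------------

def clustering_by_triangles(adj: dict) -> float:
    """Mean local clustering via explicit triangle counting.

    ``adj`` maps node -> set of neighbours.  Nodes with degree < 2
    contribute 0.
    """
    total = 0.0
    for node, nbrs in adj.items():
        k = len(nbrs)
        if k < 2:
            continue
        tri = 0
        for a, b in itertools.combinations(sorted(nbrs), 2):
            if b in adj[a]:
                tri += 1
        total += 2.0 * tri / (k * (k - 1))
    return total / len(adj)


def modularity_of_partition(edges: list[tuple], nodes: list, partition) -> float:
    """Newman-Girvan Q computed from first principles."""
    m = len(edges)
    if m == 0:
        return 0.0
    deg = {v: 0 for v in nodes}
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    comm = {}
    for ci, members in enumerate(partition):
        for v in members:
            comm[v] = ci
    q = 0.0
    for ci in range(len(partition)):
        lc = sum(1 for a, b in edges if comm[a] == ci and comm[b] == ci)
        dc = sum(d for v, d in deg.items() if comm[v] == ci)
        q += lc / m - (dc / (2.0 * m)) ** 2
    return q


def _set_partitions(items: list):
    """All set partitions via restricted growth strings."""
    n = len(items)
    if n == 0:
        yield []
        return
    rgs = [0] * n
    maxes = [0] * n
    while True:
        groups: dict[int, list] = {}
        for item, g in zip(items, rgs):
            groups.setdefault(g, []).append(item)
        yield list(groups.values())
        i = n - 1
        while i > 0:
            if rgs[i] <= maxes[i - 1]:
                rgs[i] += 1
                maxes[i] = max(maxes[i - 1], rgs[i])
                for j in range(i + 1, n):
                    rgs[j] = 0
                    maxes[j] = maxes[i]
                break
            i -= 1
        else:
            return


def optimal_modularity(edges: list[tuple], nodes: list) -> float:
    """Exhaustive search over every partition - exact optimum Q.

    Enumeration is exhaustive (restricted growth strings); per-partition Q is
    evaluated with vectorized bincounts so 10-node graphs stay tractable.
    """
    nodes = list(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    m = len(edges)
    if m == 0:
        return 0.0
    e0 = np.array([index[a] for a, b in edges])
    e1 = np.array([index[b] for a, b in edges])
    deg = np.bincount(np.concatenate([e0, e1]), minlength=len(nodes)).astype(float)
    best = -np.inf
    for part in _set_partitions(nodes):
        lab = np.empty(len(nodes), dtype=int)
        for ci, members in enumerate(part):
            for v in members:
                lab[index[v]] = ci
        lc = np.bincount(lab[e0][lab[e0] == lab[e1]], minlength=len(part))
        dc = np.bincount(lab, weights=deg, minlength=len(part))
        q = lc.sum() / m - np.sum((dc / (2.0 * m)) ** 2)
        if q > best:
            best = q
    return float(best)


# ---------------------------------------------------------------------------
# Rotations (2-factor closed forms)
# ---------------------------------------------------------------------------

def varimax_2factor(A: np.ndarray) -> np.ndarray:
    """Closed-form single-angle varimax for exactly two factors (Kaiser).

    Row-normalizes, rotates by the analytic optimum angle, denormalizes.
    """
    h = np.sqrt((A ** 2).sum(axis=1))
    B = A / h[:, None]
    p = B.shape[0]
    u = B[:, 0] ** 2 - B[:, 1] ** 2
    v = 2.0 * B[:, 0] * B[:, 1]
    As, Bs = u.sum(), v.sum()
    C = (u ** 2 - v ** 2).sum()
    D = (2.0 * u * v).sum()
    theta = 0.25 * np.arctan2(D - 2.0 * As * Bs / p, C - (As ** 2 - Bs ** 2) / p)
    R = np.array([[np.cos(theta), -np.sin(theta)],
                  [np.sin(theta), np.cos(theta)]])
    return (B @ R) * h[:, None]


def promax_2factor(A: np.ndarray, kappa: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
    """Spelled-out power-target oblique transform after closed-form varimax."""
    V = varimax_2factor(A)
    # element-wise power target, sign preserved
    target = np.empty_like(V)
    for i in range(V.shape[0]):
        for j in range(V.shape[1]):
            target[i, j] = np.sign(V[i, j]) * abs(V[i, j]) ** kappa
    U = np.linalg.solve(V.T @ V, V.T @ target)
    d = np.diag(np.linalg.inv(U.T @ U))
    U = U @ np.diag(np.sqrt(d))
    pattern = V @ U
    phi = np.linalg.inv(U.T @ U)
    return pattern, phi


def align_columns(X: np.ndarray, ref: np.ndarray) -> float:
    """Min over column permutations and sign flips of max |X - ref|."""
    k = X.shape[1]
    best = np.inf
    for perm in itertools.permutations(range(k)):
        for signs in itertools.product((1.0, -1.0), repeat=k):
            d = np.abs(X[:, perm] * np.array(signs) - ref).max()
            best = min(best, d)
    return best


# ---------------------------------------------------------------------------
# Partial correlations (KMO cross-check)
# ---------------------------------------------------------------------------

def partial_correlation_by_regression(X: np.ndarray, i: int, j: int) -> float:
    """Partial r of columns i, j given all others, via residual regression."""
    others = [c for c in range(X.shape[1]) if c not in (i, j)]
    Z = np.column_stack([np.ones(X.shape[0]), X[:, others]])
    ri = X[:, i] - Z @ np.linalg.lstsq(Z, X[:, i], rcond=None)[0]
    rj = X[:, j] - Z @ np.linalg.lstsq(Z, X[:, j], rcond=None)[0]
    return float(np.corrcoef(ri, rj)[0, 1])
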