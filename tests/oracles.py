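"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive — exhaustive enumeration or textbook
formulas — and shares no code with the implementations it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
import statsmodels.api as sm

from morbnet.ising import ebic_value


def set_partitions(items: list):
    """All partitions of a list (restricted-growth-string enumeration)."""
    items = list(items)
    n = len(items)
    if n == 0:
        yield []
        return
    rgs = [0] * n

    def expand(rgs):
        groups: dict[int, list] = {}
        for item, g in zip(items, rgs):
            groups.setdefault(g, []).append(item)
        return list(groups.values())

    while True:
        yield expand(rgs)
        # next restricted growth string
        i = n - 1
        while i > 0:
            if rgs[i] <= max(rgs[:i]):
                break
            i -= 1
        if i == 0:
            return
        rgs[i] += 1
        for j in range(i + 1, n):
            rgs[j] = 0


def modularity_of(A: np.ndarray, groups: list[list[int]]) -> float:
    """Weighted Newman modularity of a partition given an affinity matrix."""
    two_m = A.sum()
    if two_m == 0:
        return 0.0
    k = A.sum(axis=1)
    q = 0.0
    for g in groups:
        idx = np.array(g)
        q += A[np.ix_(idx, idx)].sum() / two_m - (k[idx].sum() / two_m) ** 2
    return q


def best_partition_exhaustive(A: np.ndarray) -> tuple[float, list[list[int]]]:
    """Global modularity maximum over all partitions (tiny graphs only)."""
    n = len(A)
    best_q, best_p = -np.inf, None
    for part in set_partitions(list(range(n))):
        q = modularity_of(A, part)
        if q > best_q:
            best_q, best_p = q, part
    return best_q, best_p


def shortest_paths_brute(A: np.ndarray):
    """All-pairs shortest path distances and path counts on lengths 1/|w|.

    Dijkstra-free: enumerate all simple paths (graphs are <= 8 nodes).
    Returns (dist, sigma) with sigma[i][j] the list of shortest paths.
    """
    A = np.abs(A)
    n = len(A)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    paths: dict[tuple[int, int], list[list[int]]] = {}
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            best, bp = np.inf, []
            for k in range(n - 1):
                for mid in itertools.permutations([v for v in range(n) if v not in (s, t)], k):
                    seq = [s, *mid, t]
                    ok = all(A[a, b] > 0 for a, b in zip(seq, seq[1:]))
                    if not ok:
                        continue
                    d = sum(1.0 / abs(A[a, b]) for a, b in zip(seq, seq[1:]))
                    if d < best - 1e-12:
                        best, bp = d, [seq]
                    elif abs(d - best) <= 1e-12:
                        bp.append(seq)
            dist[s, t] = best
            paths[(s, t)] = bp
    return dist, paths


def betweenness_brute(A: np.ndarray) -> np.ndarray:
    """Unnormalised betweenness: fraction of shortest paths through a node."""
    n = len(A)
    dist, paths = shortest_paths_brute(A)
    out = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            sp = paths.get((s, t), [])
            if not sp:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                through = sum(1 for seq in sp if v in seq[1:-1])
                out[v] += through / len(sp)
    return out


def closeness_brute(A: np.ndarray) -> np.ndarray:
    """(reachable - 1) / (sum of distances to reachable nodes)."""
    n = len(A)
    dist, _ = shortest_paths_brute(A)
    out = np.zeros(n)
    for i in range(n):
        finite = [dist[i, j] for j in range(n) if j != i and np.isfinite(dist[i, j])]
        if finite:
            out[i] = len(finite) / sum(finite)
    return out


def participation_brute(A: np.ndarray, labels: np.ndarray) -> np.ndarray:
    Aabs = np.abs(A)
    k = Aabs.sum(axis=1)
    out = np.zeros(len(A))
    for i in range(len(A)):
        if k[i] == 0:
            continue
        out[i] = 1.0 - sum(
            (Aabs[i, labels == c].sum() / k[i]) ** 2 for c in np.unique(labels)
        )
    return out


def exhaustive_ebic_support(X: np.ndarray, node: int, gamma: float = 0.25) -> frozenset:
    """All-subsets maximum-likelihood EBIC search for one node's neighbours."""
    n, p = X.shape
    y = X[:, node]
    others = [j for j in range(p) if j != node]
    best, best_ebic = None, np.inf
    for k in range(len(others) + 1):
        for sub in itertools.combinations(others, k):
            Z = np.column_stack([np.ones(n)] + [X[:, j] for j in sub])
            fit = sm.GLM(y, Z, family=sm.families.Binomial()).fit()
            e = float(ebic_value(fit.llf, k, n, p - 1, gamma))
            if e < best_ebic:
                best_ebic, best = e, frozenset(sub)
    return best


def poisson_sandwich_fd(X: np.ndarray, y: np.ndarray, w: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Sandwich covariance from finite-difference derivatives only.

    Bread: numerical Hessian of the weighted Poisson log pseudo-likelihood;
    meat: outer products of numerically differentiated per-person score
    contributions.
    """
    from statsmodels.tools.numdiff import approx_fprime, approx_hess

    def loglik(b):
        mu = np.exp(X @ b)
        return float(np.sum(w * (y * (X @ b) - mu)))

    H = approx_hess(beta, loglik)
    k = len(beta)
    M = np.zeros((k, k))
    for i in range(len(y)):
        def li(b, i=i):
            mu_i = np.exp(X[i] @ b)
            return float(w[i] * (y[i] * (X[i] @ b) - mu_i))

        s = approx_fprime(beta, li).ravel()
        M += np.outer(s, s)
    Hinv = np.linalg.inv(-H)
    return Hinv @ M @ Hinv
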