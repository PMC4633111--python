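"""Independent brute-force oracles used to validate the graph metrics.

Everything here is deliberately naive: explicit BFS, exhaustive
shortest-path enumeration, direct neighbor-pair counting.  None of it
shares code with the implementation under test.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations

import numpy as np


def bf_distances(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0
        q = deque([s])
        while q:
            u = q.popleft()
            for v in range(n):
                if a[u, v] and dist[s, v] == np.inf:
                    dist[s, v] = dist[s, u] + 1
                    q.append(v)
    return dist


def bf_clustering(a: np.ndarray) -> tuple[np.ndarray, float]:
    n = a.shape[0]
    cc = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if a[i, j]]
        k = len(nb)
        if k < 2:
            continue
        links = sum(1 for u, v in combinations(nb, 2) if a[u, v])
        cc[i] = links / (k * (k - 1) / 2)
    return cc, float(cc.mean())


def bf_path_length(a: np.ndarray) -> float:
    d = bf_distances(a)
    vals = [d[i, j] for i, j in combinations(range(a.shape[0]), 2) if np.isfinite(d[i, j])]
    if not vals:
        raise ValueError("no reachable pairs")
    return float(np.mean(vals))


def bf_global_efficiency(a: np.ndarray) -> float:
    n = a.shape[0]
    if n < 2:
        return 0.0
    d = bf_distances(a)
    inv = [1.0 / d[i, j] if np.isfinite(d[i, j]) and d[i, j] > 0 else 0.0
           for i, j in combinations(range(n), 2)]
    return float(np.mean(inv))


def bf_local_efficiency(a: np.ndarray) -> float:
    n = a.shape[0]
    effs = []
    for i in range(n):
        nb = [j for j in range(n) if a[i, j]]
        if len(nb) < 2:
            effs.append(0.0)
            continue
        sub = a[np.ix_(nb, nb)]
        effs.append(bf_global_efficiency(sub))
    return float(np.mean(effs))


def _all_shortest_paths(a: np.ndarray, s: int, t: int, dist: np.ndarray) -> list[list[int]]:
    """Enumerate every shortest s->t path by DFS along the BFS distance field."""
    if not np.isfinite(dist[s, t]):
        return []
    paths = []

    def walk(u: int, acc: list[int]) -> None:
        if u == t:
            paths.append(acc)
            return
        for v in range(a.shape[0]):
            if a[u, v] and dist[v, t] == dist[u, t] - 1:
                walk(v, acc + [v])

    walk(s, [s])
    return paths


def bf_betweenness(a: np.ndarray) -> np.ndarray:
    """Freeman betweenness with fractional credit, endpoints excluded."""
    n = a.shape[0]
    dist = bf_distances(a)
    b = np.zeros(n)
    for s, t in combinations(range(n), 2):
        paths = _all_shortest_paths(a, s, t, dist)
        if not paths:
            continue
        for path in paths:
            for node in path[1:-1]:
                b[node] += 1.0 / len(paths)
    return b


def gaussian_kl(mu1: float, sd1: float, mu2: float, sd2: float) -> float:
    """Closed-form KL(N1 || N2) for univariate Gaussians."""
    return (
        np.log(sd2 / sd1)
        + (sd1**2 + (mu1 - mu2) ** 2) / (2 * sd2**2)
        - 0.5
    )


def gaussian_symmetric_kl(mu1: float, sd1: float, mu2: float, sd2: float) -> float:
    return gaussian_kl(mu1, sd1, mu2, sd2) + gaussian_kl(mu2, sd2, mu1, sd1)


def bh_stepup(p: np.ndarray, alpha: float) -> np.ndarray:
    """Hand-written Benjamini-Hochberg step-up rejection flags."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    reject = np.zeros(m, dtype=bool)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * alpha / m:
            k_max = rank
    reject[order[:k_max]] = True
    return reject


def icc_oneway_longhand(x: np.ndarray) -> float:
    """One-way ICC(1,1) via sums of squares written out term by term."""
    n, k = x.shape
    grand = sum(x[i, j] for i in range(n) for j in range(k)) / (n * k)
    means = [sum(x[i, j] for j in range(k)) / k for i in range(n)]
    ssb = sum(k * (means[i] - grand) ** 2 for i in range(n))
    ssw = sum((x[i, j] - means[i]) ** 2 for i in range(n) for j in range(k))
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)
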