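"""Independent brute-force graph-metric implementations used as oracles.

Deliberately naive: Floyd–Warshall triple loops, explicit neighbor-pair
triangle counting, and geodesic counting via adjacency-matrix powers (the
number of walks of minimal length equals the number of shortest paths).
Nothing here shares code with scnet.metrics.
"""

from __future__ import annotations

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    a = np.asarray(adj, dtype=bool)
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    for i in range(n):
        dist[i, i] = 0.0
    for i in range(n):
        for j in range(n):
            if a[i, j]:
                dist[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def clustering_oracle(adj: np.ndarray) -> tuple[np.ndarray, float]:
    a = np.asarray(adj, dtype=bool)
    n = a.shape[0]
    c = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if a[i, j]]
        k = len(nb)
        if k < 2:
            continue
        links = sum(
            1 for x in range(k) for y in range(x + 1, k) if a[nb[x], nb[y]]
        )
        c[i] = links / (k * (k - 1) / 2)
    return c, float(c.mean())


def path_length_oracle(adj: np.ndarray) -> float:
    dist = floyd_warshall(adj)
    n = dist.shape[0]
    vals = [dist[i, j] for i in range(n) for j in range(i + 1, n) if np.isfinite(dist[i, j])]
    if not vals:
        raise ValueError("no connected pairs")
    return float(np.mean(vals))


def global_efficiency_oracle(adj: np.ndarray) -> float:
    dist = floyd_warshall(adj)
    n = dist.shape[0]
    if n < 2:
        return 0.0
    vals = [
        (1.0 / dist[i, j]) if np.isfinite(dist[i, j]) else 0.0
        for i in range(n)
        for j in range(i + 1, n)
    ]
    return float(np.mean(vals))


def local_efficiency_oracle(adj: np.ndarray) -> tuple[np.ndarray, float]:
    a = np.asarray(adj, dtype=bool)
    n = a.shape[0]
    eff = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if a[i, j]]
        if len(nb) >= 2:
            eff[i] = global_efficiency_oracle(a[np.ix_(nb, nb)])
    return eff, float(eff.mean())


def geodesic_counts(adj: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """sigma[s, t] = number of shortest s-t paths, via powers of A."""
    a = np.asarray(adj, dtype=np.int64)
    n = a.shape[0]
    finite = dist[np.isfinite(dist)]
    dmax = int(finite.max()) if finite.size else 0
    powers = [np.eye(n, dtype=np.int64)]
    for _ in range(dmax):
        powers.append(powers[-1] @ a)
    sigma = np.zeros((n, n), dtype=np.int64)
    for s in range(n):
        for t in range(n):
            if np.isfinite(dist[s, t]):
                sigma[s, t] = powers[int(dist[s, t])][s, t]
    return sigma


def betweenness_oracle(adj: np.ndarray) -> np.ndarray:
    """Fractional geodesic credit over unordered pairs excluding the node."""
    dist = floyd_warshall(adj)
    sigma = geodesic_counts(adj, dist)
    n = dist.shape[0]
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(dist[s, t]) or sigma[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if dist[s, v] + dist[v, t] == dist[s, t]:
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return bc


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook sum-formula Pearson correlation."""
    n = len(x)
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = np.sqrt(n * (x * x).sum() - sx**2) * np.sqrt(n * (y * y).sum() - sy**2)
    return float(num / den)


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up by the definitional formula."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adj[i] = running_min
    return np.minimum(adj, 1.0)


def random_graph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    a = (rng.random((n, n)) < p).astype(np.int8)
    a = np.triu(a, k=1)
    return a + a.T
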