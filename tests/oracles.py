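"""Independent brute-force oracles used by the test suite.

Everything here is written with plain Python loops and ``math`` so it
shares no code path with the package implementation it checks.
"""

import math
from itertools import combinations


def gaussian_density(point, center, cov):
    """3D Gaussian density via explicit cofactor inversion (no numpy.linalg)."""
    a, b, c = cov[0]
    d, e, f = cov[1]
    g, h, i = cov[2]
    det = a * (e * i - f * h) - b * (d * i - f * g) + c * (d * h - e * g)
    inv = [
        [(e * i - f * h) / det, (c * h - b * i) / det, (b * f - c * e) / det],
        [(f * g - d * i) / det, (a * i - c * g) / det, (c * d - a * f) / det],
        [(d * h - e * g) / det, (b * g - a * h) / det, (a * e - b * d) / det],
    ]
    dx = [point[m] - center[m] for m in range(3)]
    maha = sum(dx[m] * inv[m][n] * dx[n] for m in range(3) for n in range(3))
    return math.exp(-0.5 * maha) / math.sqrt((2 * math.pi) ** 3 * det)


def soft_responsibilities(point, weights, centers, covs):
    dens = [w * gaussian_density(point, mu, cov)
            for w, mu, cov in zip(weights, centers, covs)]
    total = sum(dens)
    if total == 0.0:  # all underflow: nearest center wins
        d2 = [sum((point[m] - mu[m]) ** 2 for m in range(3))
              for mu in centers]
        out = [0.0] * len(centers)
        out[d2.index(min(d2))] = 1.0
        return out
    return [d / total for d in dens]


def mdcc_direct(points_i, points_j, mix_i, mix_j, k, l):
    """Direct summation of the occupancy-weighted cosine.

    ``mix_*`` are (weights, centers, covs) tuples; returns (mdcc, mass).
    """
    wi, mui, covi = mix_i
    wj, muj, covj = mix_j
    num = di2 = dj2 = mass = 0.0
    for pi, pj in zip(points_i, points_j):
        gk = soft_responsibilities(pi, wi, mui, covi)[k]
        gl = soft_responsibilities(pj, wj, muj, covj)[l]
        gamma = gk * gl
        dik = [pi[m] - mui[k][m] for m in range(3)]
        djl = [pj[m] - muj[l][m] for m in range(3)]
        num += gamma * sum(dik[m] * djl[m] for m in range(3))
        di2 += gamma * sum(x * x for x in dik)
        dj2 += gamma * sum(x * x for x in djl)
        mass += gamma
    return num / math.sqrt(di2 * dj2), mass


def all_simple_paths(adj, s, t):
    """All simple s-t paths in an adjacency-set graph, by explicit DFS."""
    paths = []
    stack = [(s, [s])]
    while stack:
        node, path = stack.pop()
        if node == t:
            paths.append(path)
            continue
        for nxt in adj[node]:
            if nxt not in path:
                stack.append((nxt, path + [nxt]))
    return paths


def betweenness_enumerate(nodes, edges):
    """Unnormalised betweenness by exhaustive path enumeration.

    Unordered pairs (s < t), endpoints excluded, disconnected pairs
    contribute nothing.
    """
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    g = {n: 0.0 for n in nodes}
    for s, t in combinations(sorted(nodes), 2):
        paths = all_simple_paths(adj, s, t)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        short = [p for p in paths if len(p) == shortest]
        for i in nodes:
            if i in (s, t):
                continue
            g[i] += sum(1 for p in short if i in p) / len(short)
    return g
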