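"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the library code paths (scipy.csgraph, networkx):
distances via a triple-loop Floyd-Warshall, triangles and neighbourhoods via
explicit Python loops.
"""

import numpy as np


def floyd_warshall(W):
    """All-pairs shortest paths with edge length 1/weight, pure loops."""
    n = W.shape[0]
    d = np.full((n, n), np.inf)
    for i in range(n):
        d[i, i] = 0.0
        for j in range(n):
            if i != j and W[i, j] > 0:
                d[i, j] = 1.0 / W[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def strength_brute(W):
    return np.array([sum(W[i, j] for j in range(W.shape[0])) for i in range(W.shape[0])])


def char_path_length_brute(W):
    d = floyd_warshall(W)
    n = W.shape[0]
    per_node = []
    for i in range(n):
        vals = [d[i, j] for j in range(n) if j != i and np.isfinite(d[i, j])]
        if vals:
            per_node.append(sum(vals) / len(vals))
    return sum(per_node) / len(per_node)


def global_efficiency_brute(W):
    d = floyd_warshall(W)
    n = W.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def clustering_brute(W):
    n = W.shape[0]
    C = []
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        k = len(nbrs)
        t = 0.0
        for j in range(n):
            for h in range(n):
                t += (W[i, j] * W[i, h] * W[j, h]) ** (1 / 3)
        t /= 2.0
        C.append(2 * t / (k * (k - 1)) if k >= 2 else 0.0)
    return sum(C) / n


def local_efficiency_brute(W):
    n = W.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        sub = W[np.ix_(nbrs, nbrs)]
        dsub = floyd_warshall(sub)
        acc = 0.0
        for a in range(k):
            for b in range(k):
                if a != b and np.isfinite(dsub[a, b]) and dsub[a, b] > 0:
                    acc += (W[i, nbrs[a]] * W[i, nbrs[b]] / dsub[a, b]) ** (1 / 3)
        total += acc / (k * (k - 1))
    return total / n


def random_weighted_graph(n, density, rng):
    """Random symmetric weighted graph with weights in (0, 1]."""
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                W[i, j] = W[j, i] = rng.uniform(0.05, 1.0)
    return W
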