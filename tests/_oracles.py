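"""Independent brute-force implementations used only as test oracles.

Everything here is deliberately naive (explicit loops, exhaustive path
enumeration, Floyd-Warshall) and shares no code with the package.
"""

from itertools import permutations

import numpy as np


def strength_loop(w):
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i] += w[i, j]
    return out


def clustering_loop(w):
    """Onnela geometric-mean clustering with max-normalized weights."""
    n = w.shape[0]
    wmax = max(w[i, j] for i in range(n) for j in range(n) if i != j)
    if wmax == 0:
        return np.zeros(n)
    out = np.zeros(n)
    for i in range(n):
        k = sum(1 for j in range(n) if j != i and w[i, j] > 0)
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    total += (w[i, j] / wmax * w[i, h] / wmax
                              * w[j, h] / wmax) ** (1.0 / 3.0)
        out[i] = total / (k * (k - 1))
    return out


def floyd_warshall(lengths):
    """All-pairs shortest paths; lengths of 0 mean no edge."""
    n = lengths.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and lengths[i, j] > 0:
                d[i, j] = lengths[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def global_efficiency_loop(w):
    """Weighted global efficiency with reciprocal-weight lengths."""
    n = w.shape[0]
    if n < 2:
        return 0.0
    lengths = np.zeros_like(w, dtype=float)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                lengths[i, j] = 1.0 / w[i, j]
    d = floyd_warshall(lengths)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def local_efficiency_loop(w, normalize=True):
    n = w.shape[0]
    wmax = w.max() if normalize else 1.0
    if wmax == 0:
        return np.zeros(n)
    wn = w / wmax
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if j != i and wn[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = wn[np.ix_(nbrs, nbrs)]
        out[i] = global_efficiency_loop(sub)
    return out


def betweenness_paths(w, rel_tol=1e-12):
    """Betweenness by exhaustive simple-path enumeration.

    For every unordered pair, all simple paths are enumerated, the shortest
    length (sum of reciprocal weights) is found, and every interior node of
    every shortest path receives fractional credit 1/#shortest-paths.
    """
    n = w.shape[0]
    out = np.zeros(n)
    nodes = list(range(n))
    adj = {i: [j for j in nodes if j != i and w[i, j] > 0] for i in nodes}

    def simple_paths(s, t):
        stack = [(s, [s], 0.0)]
        while stack:
            node, path, length = stack.pop()
            if node == t:
                yield path, length
                continue
            for nxt in adj[node]:
                if nxt not in path:
                    stack.append((nxt, path + [nxt],
                                  length + 1.0 / w[node, nxt]))

    for s in range(n):
        for t in range(s + 1, n):
            paths = list(simple_paths(s, t))
            if not paths:
                continue
            best = min(length for _, length in paths)
            shortest = [p for p, length in paths
                        if length <= best * (1 + rel_tol)]
            credit = 1.0 / len(shortest)
            for p in shortest:
                for node in p[1:-1]:
                    out[node] += credit
    return out


def binary_clustering_loop(adj):
    """Textbook unweighted clustering: triangles over connected triples."""
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if j != i and adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(1 for a, b in permutations(nbrs, 2) if a < b and adj[a, b])
        out[i] = 2.0 * links / (k * (k - 1))
    return out


def pairwise_kuramoto_loop(theta_x, theta_y):
    out = np.empty(len(theta_x))
    for t in range(len(theta_x)):
        out[t] = abs((np.exp(1j * theta_x[t]) + np.exp(1j * theta_y[t])) / 2)
    return out


def roi_means_loop(bold, atlas, labels):
    """Per-voxel loop over a 4-D volume, averaging within each label."""
    nx, ny, nz, nt = bold.shape
    out = np.zeros((len(labels), nt))
    for r, lab in enumerate(labels):
        count = 0
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    if atlas[x, y, z] == lab:
                        out[r] += bold[x, y, z]
                        count += 1
        out[r] /= count
    return out
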