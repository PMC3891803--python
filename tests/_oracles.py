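"""Independent brute-force graph-metric oracles for cross-checking.

Everything here enumerates simple paths explicitly — exponential, but exact
— and is deliberately kept free of any code shared with the package's
matrix-power implementation.
"""

from itertools import combinations

import numpy as np


def all_simple_paths(adj, a, b):
    """Every simple path from a to b as a list of node tuples (DFS)."""
    n = len(adj)
    out = []

    def dfs(node, visited, path):
        if node == b:
            out.append(tuple(path))
            return
        for nb in range(n):
            if adj[node][nb] and nb not in visited:
                visited.add(nb)
                path.append(nb)
                dfs(nb, visited, path)
                path.pop()
                visited.remove(nb)

    dfs(a, {a}, [a])
    return out


def brute_force_metrics(adj):
    """(degree, clustering, betweenness, L, connected_pair_fraction, dist, counts).

    Distances and geodesic counts come from exhaustive simple-path
    enumeration; betweenness counts interior nodes of every geodesic;
    clustering counts neighbour links literally.
    """
    adj = np.asarray(adj)
    n = len(adj)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    counts = np.zeros((n, n))
    np.fill_diagonal(counts, 1.0)
    geodesics = {}
    for a, b in combinations(range(n), 2):
        paths = all_simple_paths(adj, a, b)
        if not paths:
            continue
        d = min(len(p) - 1 for p in paths)
        geo = [p for p in paths if len(p) - 1 == d]
        dist[a, b] = dist[b, a] = d
        counts[a, b] = counts[b, a] = len(geo)
        geodesics[(a, b)] = geo

    deg = adj.sum(axis=1)

    clu = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(adj[u][v] for u, v in combinations(nbrs, 2))
        clu[i] = links / (k * (k - 1) / 2)

    bet = np.zeros(n)
    for (a, b), geo in geodesics.items():
        for i in range(n):
            if i in (a, b):
                continue
            through = sum(1 for p in geo if i in p)
            bet[i] += through / len(geo)

    iu, ju = np.triu_indices(n, k=1)
    d = dist[iu, ju]
    finite = np.isfinite(d)
    l_avg = float(d[finite].mean()) if finite.any() else float("nan")
    return deg, clu, bet, l_avg, float(finite.mean()), dist, counts
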