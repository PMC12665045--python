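"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use naive enumeration (DFS over all simple paths,
triple loops over neighbor pairs, explicit summation) and share no code
with the package internals.
"""

from __future__ import annotations

import numpy as np


def random_adjacency(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    """Symmetric zero-diagonal 0/1 matrix with edge probability p."""
    upper = rng.random((n, n)) < p
    a = np.triu(upper, k=1)
    return (a | a.T).astype(np.int8)


def brute_degree(a: np.ndarray, i: int) -> int:
    count = 0
    for j in range(a.shape[0]):
        if j != i and a[i, j]:
            count += 1
    return count


def brute_clustering(a: np.ndarray, i: int) -> float:
    """Triangle enumeration over neighbor pairs; CC = 1 when degree < 2."""
    nbrs = [j for j in range(a.shape[0]) if j != i and a[i, j]]
    d = len(nbrs)
    if d < 2:
        return 1.0
    triangles = 0
    for x in range(d):
        for y in range(x + 1, d):
            if a[nbrs[x], nbrs[y]]:
                triangles += 1
    return triangles / (d * (d - 1) / 2)


def _all_simple_paths(a: np.ndarray, x: int, y: int) -> list[tuple[int, ...]]:
    n = a.shape[0]
    out: list[tuple[int, ...]] = []

    def dfs(node: int, visited: set[int], path: list[int]) -> None:
        if node == y:
            out.append(tuple(path))
            return
        for nxt in range(n):
            if a[node, nxt] and nxt not in visited:
                visited.add(nxt)
                path.append(nxt)
                dfs(nxt, visited, path)
                path.pop()
                visited.remove(nxt)

    dfs(x, {x}, [x])
    return out


def brute_betweenness(a: np.ndarray) -> np.ndarray:
    """Enumerate all simple paths per unordered pair, keep the shortest,
    and count pass-throughs.  Disconnected pairs contribute 0."""
    n = a.shape[0]
    b = np.zeros(n)
    for x in range(n):
        for y in range(x + 1, n):
            paths = _all_simple_paths(a, x, y)
            if not paths:
                continue
            minlen = min(len(p) for p in paths)
            shortest = [p for p in paths if len(p) == minlen]
            for i in range(n):
                if i in (x, y):
                    continue
                through = sum(1 for p in shortest if i in p)
                b[i] += through / len(shortest)
    return b
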