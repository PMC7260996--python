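"""Independent brute-force oracles used only by the tests.

These deliberately re-derive results by enumeration so they share no code
path with the package implementations they check.
"""

from __future__ import annotations

import numpy as np


def mum_oracle(a: str, b: str, min_len: int) -> set[tuple[int, int, int]]:
    """All maximal matches unique in both strings, by diagonal enumeration.

    Builds the full character-equality matrix, extracts maximal runs on
    every diagonal (maximality in both directions is automatic), then
    keeps runs whose substring occurs exactly once in each input.
    """
    A = np.frombuffer(a.encode(), dtype=np.uint8)
    B = np.frombuffer(b.encode(), dtype=np.uint8)
    eq = A[:, None] == B[None, :]
    n, m = len(a), len(b)
    out: set[tuple[int, int, int]] = set()
    for d in range(-(m - 1), n):
        i0, j0 = (d, 0) if d >= 0 else (0, -d)
        L = min(n - i0, m - j0)
        diag = eq[i0 + np.arange(L), j0 + np.arange(L)]
        edges = np.flatnonzero(np.diff(np.concatenate(([0], diag.view(np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            if e - s >= min_len:
                sub = a[i0 + s : i0 + e]
                if a.count(sub) == 1 and b.count(sub) == 1:
                    out.add((i0 + s, j0 + s, e - s))
    return out


def dbscan_oracle(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Density-reachability BFS over the eps-neighborhood graph.

    Core points have >= min_pts neighbors within eps (self included);
    clusters grow by BFS from core points in input order; border points
    join the first cluster that reaches them; the rest is noise.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    neigh = d2 <= eps**2 + 1e-15
    core = neigh.sum(axis=1) >= min_pts
    labels = np.full(n, -1, dtype=int)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        labels[i] = cluster
        queue = [i]
        while queue:
            u = queue.pop(0)
            for v in np.flatnonzero(neigh[u]):
                if labels[v] == -1:
                    labels[v] = cluster
                    if core[v]:
                        queue.append(v)
        cluster += 1
    return labels


def canonical_partition(labels) -> tuple[frozenset, frozenset]:
    """(set of clusters as frozensets of indices, noise indices)."""
    labels = np.asarray(labels)
    clusters = frozenset(
        frozenset(np.flatnonzero(labels == c).tolist()) for c in set(labels) if c != -1
    )
    noise = frozenset(np.flatnonzero(labels == -1).tolist())
    return clusters, noise


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
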