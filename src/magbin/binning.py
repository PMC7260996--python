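"""Co-abundance binning of scaftigs into scaftig-linkage groups (SLGs).

Scaftigs that originate from one genome rise and fall together across
samples, so their depth profiles correlate strongly.  A correlation graph
(edge iff Pearson r > 0.7) is agglomerated greedily under an edge-density
constraint: two groups merge only while the fraction of realized
cross-edges between them stays at or above ``density_min`` (default 0.99).
Groups whose total length exceeds ``min_length`` are emitted as preliminary
SLGs.

The merge schedule is this package's own: repeatedly join the pair of
groups with the highest inter-group edge density, breaking ties by larger
combined length and then by lexicographically smallest member id, which
makes the output independent of input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from ._sequtils import n50 as _n50


@dataclass
class CorrelationGraph:
    nodes: list[str]
    edges: dict[frozenset, float]
    r_threshold: float = 0.7

    def neighbors(self, node: str) -> set[str]:
        return {next(iter(e - {node})) for e in self.edges if node in e}


@dataclass
class SLG:
    """A scaftig-linkage group."""

    id: str
    members: set[str]
    total_length: int
    n50: int
    status: str = "preliminary"
    mean_depth: float = float("nan")
    sequences: dict[str, str] = field(default_factory=dict)


def pearson(x, y) -> float:
    """Pearson correlation; raises on constant input (undefined r)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("pearson: need two equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson: correlation undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


def build_graph(depths: pd.DataFrame, r_threshold: float = 0.7) -> CorrelationGraph:
    """Correlation graph over scaftigs: edge iff Pearson r > r_threshold.

    Constant (zero-variance) depth rows have undefined correlation and get
    no edges.
    """
    if depths.shape[1] < 3:
        raise ValueError("build_graph: need at least 3 samples")
    ids = list(depths.index.astype(str))
    vals = depths.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(vals)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    edges: dict[frozenset, float] = {}
    iu, ju = np.triu_indices(len(ids), k=1)
    hit = np.flatnonzero(np.nan_to_num(r[iu, ju], nan=-2.0) > r_threshold)
    for k in hit:
        i, j = int(iu[k]), int(ju[k])
        edges[frozenset((ids[i], ids[j]))] = float(r[i, j])
    return CorrelationGraph(nodes=ids, edges=edges, r_threshold=r_threshold)


def edge_density(graph: CorrelationGraph, group_a: set, group_b: set) -> float:
    """Fraction of realized a-b edges: |present| / (|a| * |b|)."""
    if not group_a or not group_b:
        raise ValueError("edge_density: empty group")
    if group_a & group_b:
        raise ValueError("edge_density: groups overlap")
    present = sum(1 for a in group_a for b in group_b if frozenset((a, b)) in graph.edges)
    return present / (len(group_a) * len(group_b))


def cluster_slgs(
    graph: CorrelationGraph,
    lengths: dict[str, int] | pd.Series,
    density_min: float = 0.99,
    min_length: int = 1_000_000,
) -> list[SLG]:
    """Greedy density-constrained agglomeration into preliminary SLGs.

    Starting from singletons, repeatedly merge the pair of groups with the
    highest inter-group edge density while it is >= ``density_min``.
    Ties: larger combined length first, then lexicographically smallest
    member id.  Only groups with total length > ``min_length`` are emitted.
    """
    lengths = dict(lengths) if not isinstance(lengths, dict) else lengths
    nodes = sorted(graph.nodes)
    k = len(nodes)
    if k == 0:
        return []
    pos = {n: i for i, n in enumerate(nodes)}
    A = np.zeros((k, k), dtype=np.float64)
    for e in graph.edges:
        u, v = tuple(e)
        A[pos[u], pos[v]] = A[pos[v], pos[u]] = 1.0

    members: list[set[str] | None] = [{n} for n in nodes]
    cross = A.copy()                       # cross-edge counts between groups
    size = np.ones(k)
    glen = np.array([lengths[n] for n in nodes], dtype=np.float64)
    min_id = list(nodes)                   # lexicographic representative
    alive = np.ones(k, dtype=bool)

    while alive.sum() > 1:
        live = np.flatnonzero(alive)
        D = cross[np.ix_(live, live)] / np.outer(size[live], size[live])
        np.fill_diagonal(D, -1.0)
        dmax = D.max()
        if dmax < density_min:
            break
        ii, jj = np.nonzero(D >= dmax - 1e-12)
        best = None
        for a, b in zip(ii, jj):
            if a >= b:
                continue
            gi, gj = int(live[a]), int(live[b])
            key = (-(glen[gi] + glen[gj]), min(min_id[gi], min_id[gj]), max(min_id[gi], min_id[gj]))
            if best is None or key < best[0]:
                best = (key, gi, gj)
        _, gi, gj = best
        members[gi] |= members[gj]
        members[gj] = None
        cross[gi, :] += cross[gj, :]
        cross[:, gi] += cross[:, gj]
        cross[gi, gi] = 0.0
        size[gi] += size[gj]
        glen[gi] += glen[gj]
        min_id[gi] = min(min_id[gi], min_id[gj])
        alive[gj] = False
        cross[gj, :] = 0.0
        cross[:, gj] = 0.0

    groups = [m for m in members if m is not None and sum(lengths[x] for x in m) > min_length]
    groups.sort(key=lambda m: (-sum(lengths[x] for x in m), min(m)))
    slgs = []
    for i, m in enumerate(groups, start=1):
        lens = [lengths[x] for x in m]
        slgs.append(
            SLG(id=f"slg_{i:04d}", members=set(m), total_length=sum(lens), n50=_n50(lens))
        )
    return slgs


class SLGBinner(BaseEstimator, ClusterMixin):
    """Bin scaftigs into SLGs from their depth profiles across samples.

    Parameters
    ----------
    r_threshold : float, default=0.7
        Pearson correlation above which two scaftigs are linked.
    density_min : float, default=0.99
        Minimum inter-group edge density for a merge.
    min_length : int, default=1_000_000
        Minimum total length (bp, exclusive) for an emitted SLG.

    Attributes
    ----------
    graph_ : CorrelationGraph
    slgs_ : list of SLG
    labels_ : ndarray of shape (n_scaftigs,)
        SLG index per input row; -1 for scaftigs not in any emitted SLG.
    """

    def __init__(self, r_threshold: float = 0.7, density_min: float = 0.99,
                 min_length: int = 1_000_000):
        self.r_threshold = r_threshold
        self.density_min = density_min
        self.min_length = min_length

    def fit(self, X, y=None, lengths=None):
        """Fit on a scaftigs x samples depth matrix.

        ``X`` may be a DataFrame (index = scaftig ids) or an array (rows
        named by position).  ``lengths`` maps scaftig id -> bp; required.
        """
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.index = [str(i) for i in X.index]
        if (X.to_numpy() < 0).any():
            raise ValueError("SLGBinner: negative depths")
        if lengths is None:
            raise ValueError("SLGBinner.fit requires scaftig lengths")
        self.graph_ = build_graph(X, r_threshold=self.r_threshold)
        self.slgs_ = cluster_slgs(self.graph_, lengths,
                                  density_min=self.density_min,
                                  min_length=self.min_length)
        assign = {m: i for i, slg in enumerate(self.slgs_) for m in slg.members}
        self.labels_ = np.array([assign.get(str(i), -1) for i in X.index])
        return self

    def fit_predict(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).labels_
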