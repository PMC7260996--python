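"""GC x depth refinement of preliminary SLGs.

A clean SLG holds scaftigs from one genome, which form a single tight blob
when GC content is plotted against mean aligned depth.  Chimeric SLGs show
two or more blobs; contaminated or spurious ones scatter.  DBSCAN on the
scaled (gc, depth) plane decides the verdict:

* one cluster, noise fraction <= ``noise_max``  -> qualified
* no cluster, or noise fraction > ``noise_max`` -> scattered_discard
* >= 2 clusters and SLG N50 < ``n50_min``       -> fragmented_discard
* >= 2 clusters otherwise                       -> split by cluster label;
  a child is retained only when its length-weighted mean depth exceeds
  ``depth_min``.

GC is already in [0, 1]; depth is mapped through log10(1 + depth) and
min-max scaled to [0, 1] within each SLG so the Euclidean ``eps`` radius is
meaningful on both axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import DBSCAN

from .binning import SLG


@dataclass
class GcDepthPoint:
    scaftig_id: str
    gc: float
    depth: float          # mean across samples
    length: int = 1


@dataclass
class RefinementVerdict:
    slg_id: str
    verdict: str          # qualified | scattered_discard | fragmented_discard | split
    children: list[set] = field(default_factory=list)
    mean_depth_per_child: list[float] = field(default_factory=list)
    retained_children: list[set] = field(default_factory=list)
    noise_fraction: float = 0.0
    n_clusters: int = 0


def dbscan(points, eps: float = 0.10, min_pts: int = 49) -> np.ndarray:
    """Density-based clustering of 2-D points; -1 marks noise.

    A core point has >= ``min_pts`` points (itself included) within
    Euclidean distance ``eps``; clusters are maximal density-connected
    sets.  Cluster indices follow the order of first appearance in the
    input.
    """
    if eps <= 0:
        raise ValueError("dbscan: eps must be > 0")
    if min_pts < 1:
        raise ValueError("dbscan: min_pts must be >= 1")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("dbscan: expected an (n, 2) array")
    raw = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(pts)
    # pin label order to first occurrence in input order
    remap: dict[int, int] = {}
    out = np.full(len(raw), -1, dtype=int)
    for i, lab in enumerate(raw):
        if lab == -1:
            continue
        if lab not in remap:
            remap[lab] = len(remap)
        out[i] = remap[lab]
    return out


def scale_points(points: list[GcDepthPoint], span_floor: float = 1.0) -> np.ndarray:
    """(gc, scaled depth) coordinates in [0, 1]^2 for one SLG.

    Depth goes through log10(1 + depth) and is min-max scaled, but the
    span is floored at ``span_floor`` decades: an SLG whose depths differ
    only by noise carries no structure on the depth axis, and a bare
    min-max would amplify that noise into spurious clusters.
    """
    gc = np.array([p.gc for p in points])
    d = np.log10(1.0 + np.array([p.depth for p in points]))
    denom = max(d.max() - d.min(), span_floor)
    return np.column_stack([gc, (d - d.min()) / denom])


def _weighted_depth(points: list[GcDepthPoint]) -> float:
    w = np.array([p.length for p in points], dtype=float)
    d = np.array([p.depth for p in points], dtype=float)
    return float((w * d).sum() / w.sum())


def refine_slg(
    slg: SLG,
    points: list[GcDepthPoint],
    eps: float = 0.10,
    min_pts: int = 49,
    noise_max: float = 0.5,
    n50_min: int = 2000,
    depth_min: float = 20.0,
) -> RefinementVerdict:
    """Refinement verdict for one preliminary SLG (rules in module docstring)."""
    ids = {p.scaftig_id for p in points}
    if ids != slg.members:
        raise ValueError(f"refine_slg: points do not match members of {slg.id}")
    labels = dbscan(scale_points(points), eps=eps, min_pts=min_pts)
    k = int(labels.max()) + 1 if (labels >= 0).any() else 0
    noise_frac = float((labels == -1).mean())
    v = RefinementVerdict(slg_id=slg.id, verdict="", noise_fraction=noise_frac, n_clusters=k)
    if k == 1 and noise_frac <= noise_max:
        v.verdict = "qualified"
        return v
    if k <= 1:
        v.verdict = "scattered_discard"
        return v
    if slg.n50 < n50_min:
        v.verdict = "fragmented_discard"
        return v
    v.verdict = "split"
    for c in range(k):
        child_pts = [p for p, lab in zip(points, labels) if lab == c]
        child = {p.scaftig_id for p in child_pts}
        depth = _weighted_depth(child_pts)
        v.children.append(child)
        v.mean_depth_per_child.append(depth)
        if depth > depth_min:
            v.retained_children.append(child)
    return v


class GcDepthRefiner(BaseEstimator):
    """Refine preliminary SLGs in GC x depth space.

    Parameters mirror :func:`refine_slg`.  After :meth:`fit`,
    ``verdicts_`` holds one RefinementVerdict per input SLG and
    ``qualified_`` the surviving SLGs (qualified SLGs unchanged; retained
    split children as new SLGs suffixed ``.1``, ``.2`` ...).
    """

    def __init__(self, eps: float = 0.10, min_pts: int = 49, noise_max: float = 0.5,
                 n50_min: int = 2000, depth_min: float = 20.0):
        self.eps = eps
        self.min_pts = min_pts
        self.noise_max = noise_max
        self.n50_min = n50_min
        self.depth_min = depth_min

    def fit(self, slgs: list[SLG], y=None, points: pd.DataFrame = None):
        """``points``: DataFrame indexed by scaftig id with columns
        ``gc``, ``depth`` (mean across samples) and ``length``."""
        if points is None:
            raise ValueError("GcDepthRefiner.fit requires per-scaftig points")
        from ._sequtils import n50 as _n50

        self.verdicts_ = []
        self.qualified_ = []
        for slg in slgs:
            pts = [
                GcDepthPoint(m, float(points.at[m, "gc"]), float(points.at[m, "depth"]),
                             int(points.at[m, "length"]))
                for m in sorted(slg.members)
            ]
            v = refine_slg(slg, pts, eps=self.eps, min_pts=self.min_pts,
                           noise_max=self.noise_max, n50_min=self.n50_min,
                           depth_min=self.depth_min)
            self.verdicts_.append(v)
            if v.verdict == "qualified":
                q = SLG(id=slg.id, members=set(slg.members), total_length=slg.total_length,
                        n50=slg.n50, status="qualified",
                        mean_depth=_weighted_depth(pts))
                self.qualified_.append(q)
            elif v.verdict == "split":
                for i, child in enumerate(v.retained_children, start=1):
                    lens = [int(points.at[m, "length"]) for m in child]
                    self.qualified_.append(
                        SLG(id=f"{slg.id}.{i}", members=set(child), total_length=sum(lens),
                            n50=_n50(lens), status="qualified",
                            mean_depth=v.mean_depth_per_child[
                                v.children.index(child)])
                    )
        return self
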