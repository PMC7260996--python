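"""End-to-end MAG construction: co-abundance binning, GC x depth
refinement, MUMi dereplication, overlap merging and final filtering.

``MagPipeline`` chains the three estimator stages:

1. :class:`~magbin.binning.SLGBinner` bins scaftigs into preliminary SLGs
   from their depth correlation across samples.
2. :class:`~magbin.refine.GcDepthRefiner` keeps single-cluster SLGs,
   discards scattered/fragmented ones and splits chimeric ones.
3. :class:`~magbin.mumi.MumiClusterer` dereplicates qualified SLGs by MUM
   similarity; unclustered SLGs become singleton MAGs and clusters are
   merged into combined MAGs, whose GC pattern is re-examined with the
   Step-2 rules (splits resolved against the original SLGs).

Final MAGs must exceed ``mag_min_size`` bp.  All thresholds default to
the genome-scale values (1 Mb lengths, MinPts 49); desk-scale synthetic
communities pass scaled-down thresholds instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._sequtils import gc_content
from .binning import SLG, SLGBinner
from .mumi import MAG, MumiClusterer, finalize_mags
from .profiles import zero_low_coverage
from .refine import GcDepthRefiner, dbscan, scale_points, GcDepthPoint


def _longest_overlap(sa: str, sb: str, min_overlap: int) -> int:
    """Longest exact suffix(sa) == prefix(sb) of length >= min_overlap."""
    limit = min(len(sa), len(sb))
    if limit < min_overlap:
        return 0
    probe = sb[:min_overlap]
    pos = sa.find(probe, len(sa) - limit)
    while pos != -1:
        k = len(sa) - pos
        if sa[pos:] == sb[:k]:
            return k
        pos = sa.find(probe, pos + 1)
    return 0


def merge_scaftigs(sequences: dict[str, str], min_overlap: int = 500) -> dict[str, str]:
    """Greedy longest-overlap-first exact merging (fast path of
    :func:`magbin.mumi.merge_overlap` used by the pipeline)."""
    seqs = dict(sequences)
    while len(seqs) > 1:
        best = None
        for ida, sa in seqs.items():
            for idb, sb in seqs.items():
                if ida == idb:
                    continue
                k = _longest_overlap(sa, sb, min_overlap)
                if k >= min_overlap:
                    key = (-k, ida, idb)
                    if best is None or key < best[0]:
                        best = (key, ida, idb, k)
        if best is None:
            break
        _, ida, idb, k = best
        merged = seqs[ida] + seqs[idb][k:]
        del seqs[ida], seqs[idb]
        seqs[f"{ida}+{idb}"] = merged
    return seqs


class MagPipeline(BaseEstimator):
    """Scaftig depths + sequences -> final MAGs.

    Parameters
    ----------
    r_threshold, density_min, slg_min_length
        SLG binning stage (Pearson edge cutoff, merge density, minimum
        SLG length in bp).
    eps, min_pts, noise_max, n50_min, depth_min
        GC x depth refinement stage.
    mumi_threshold, min_mum
        MUMi dereplication stage.
    min_overlap
        Minimum reliable exact scaftig overlap (bp) when merging combined
        MAGs; shorter overlaps are left unmerged.
    submag_coverage
        Minimum fraction of an original SLG a sub-MAG must retain to stand
        as a revised MAG.
    mag_min_size
        Final MAG size filter in bp (strict >).
    coverage_cutoff
        Depth entries with breadth of coverage below this are zeroed
        before binning (when a coverage matrix is supplied).

    Attributes
    ----------
    slgs_, verdicts_, qualified_, mumi_matrix_, clusters_, mags_
    assignment_ : dict scaftig id -> MAG id
    labels_ : MAG index per input row (-1 = unassigned)
    """

    def __init__(
        self,
        r_threshold: float = 0.7,
        density_min: float = 0.99,
        slg_min_length: int = 1_000_000,
        eps: float = 0.10,
        min_pts: int = 49,
        noise_max: float = 0.5,
        n50_min: int = 2000,
        depth_min: float = 20.0,
        mumi_threshold: float = 0.54,
        min_mum: int = 20,
        min_overlap: int = 500,
        submag_coverage: float = 0.90,
        mag_min_size: int = 1_000_000,
        coverage_cutoff: float = 0.1,
    ):
        self.r_threshold = r_threshold
        self.density_min = density_min
        self.slg_min_length = slg_min_length
        self.eps = eps
        self.min_pts = min_pts
        self.noise_max = noise_max
        self.n50_min = n50_min
        self.depth_min = depth_min
        self.mumi_threshold = mumi_threshold
        self.min_mum = min_mum
        self.min_overlap = min_overlap
        self.submag_coverage = submag_coverage
        self.mag_min_size = mag_min_size
        self.coverage_cutoff = coverage_cutoff

    # -- stage helpers -------------------------------------------------
    def _points(self, sequences: dict[str, str], depths: pd.DataFrame) -> pd.DataFrame:
        mean_depth = depths.mean(axis=1)
        return pd.DataFrame(
            {
                "gc": [gc_content(sequences[s]) for s in depths.index],
                "depth": mean_depth.to_numpy(),
                "length": [len(sequences[s]) for s in depths.index],
            },
            index=depths.index,
        )

    def _candidate_mag(self, cluster_slgs: list[SLG], sequences, points) -> list[MAG]:
        """Step-3 reconstruction of one multi-SLG cluster."""
        member_ids = sorted(set().union(*(s.members for s in cluster_slgs)))
        cid = "+".join(s.id for s in cluster_slgs)
        pts = [GcDepthPoint(m, points.at[m, "gc"], points.at[m, "depth"],
                            int(points.at[m, "length"])) for m in member_ids]
        labels = dbscan(scale_points(pts), eps=self.eps, min_pts=self.min_pts)
        k = int(labels.max()) + 1 if (labels >= 0).any() else 0
        if k < 2:
            seqs = merge_scaftigs({m: sequences[m] for m in member_ids}, self.min_overlap)
            return [MAG(id=f"mag_{cid}", provenance="combined", member_sequences=seqs)]
        # chimeric candidate: split into sub-MAGs, resolve against SLGs
        out: list[MAG] = []
        replaced: set[str] = set()
        slg_of = {m: s for s in cluster_slgs for m in s.members}
        for c in range(k):
            child = [m for m, lab in zip(member_ids, labels) if lab == c]
            # original SLG = the one contributing most bp to this sub-MAG
            bp: dict[str, int] = {}
            for m in child:
                bp[slg_of[m].id] = bp.get(slg_of[m].id, 0) + int(points.at[m, "length"])
            orig = max(sorted(bp), key=lambda x: bp[x])
            orig_slg = next(s for s in cluster_slgs if s.id == orig)
            orig_total = sum(int(points.at[m, "length"]) for m in orig_slg.members)
            shared = sum(int(points.at[m, "length"]) for m in child if m in orig_slg.members)
            if orig_total > 0 and shared / orig_total >= self.submag_coverage:
                seqs = merge_scaftigs({m: sequences[m] for m in child}, self.min_overlap)
                out.append(MAG(id=f"mag_{cid}.{c + 1}", provenance="revised",
                               member_sequences=seqs))
            elif orig not in replaced:
                replaced.add(orig)
                seqs = merge_scaftigs(
                    {m: sequences[m] for m in sorted(orig_slg.members)}, self.min_overlap
                )
                out.append(MAG(id=f"mag_{orig}.revised", provenance="revised",
                               member_sequences=seqs))
        return out

    # -- sklearn surface ----------------------------------------------
    def fit(self, X: pd.DataFrame, y=None, sequences: dict[str, str] = None,
            coverage: pd.DataFrame = None):
        """Fit on a scaftigs x samples depth matrix.

        ``sequences`` maps scaftig id -> nucleotide string (required);
        ``coverage`` optionally triggers the low-coverage zeroing rule.
        """
        if sequences is None:
            raise ValueError("MagPipeline.fit requires scaftig sequences")
        depths = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        missing = [s for s in depths.index if s not in sequences]
        if missing:
            raise KeyError(f"MagPipeline: no sequence for scaftig(s) {missing[:5]}")
        if coverage is not None:
            depths = zero_low_coverage(depths, coverage, cutoff=self.coverage_cutoff)
        lengths = {s: len(sequences[s]) for s in depths.index}

        self.binner_ = SLGBinner(self.r_threshold, self.density_min, self.slg_min_length)
        self.binner_.fit(depths, lengths=lengths)
        self.slgs_ = self.binner_.slgs_

        points = self._points(sequences, depths)
        self.refiner_ = GcDepthRefiner(self.eps, self.min_pts, self.noise_max,
                                       self.n50_min, self.depth_min)
        self.refiner_.fit(self.slgs_, points=points)
        self.verdicts_ = self.refiner_.verdicts_
        self.qualified_ = self.refiner_.qualified_
        for slg in self.qualified_:
            slg.sequences = {m: sequences[m] for m in sorted(slg.members)}

        seq_sets = {s.id: [s.sequences[m] for m in sorted(s.members)] for s in self.qualified_}
        mags: list[MAG] = []
        if seq_sets:
            self.derep_ = MumiClusterer(self.mumi_threshold, self.min_mum).fit(seq_sets)
            self.mumi_matrix_ = self.derep_.mumi_matrix_
            self.clusters_ = self.derep_.clusters_
            by_id = {s.id: s for s in self.qualified_}
            for cluster in self.clusters_:
                if len(cluster) == 1:
                    slg = by_id[cluster[0]]
                    mags.append(MAG(id=f"mag_{slg.id}", provenance="singleton",
                                    member_sequences=dict(slg.sequences)))
                else:
                    mags.extend(self._candidate_mag([by_id[c] for c in cluster],
                                                    sequences, points))
        else:
            self.clusters_ = []
            self.mumi_matrix_ = np.zeros((0, 0))
        self.mags_ = finalize_mags(mags, min_size=self.mag_min_size)

        self.assignment_ = {}
        for mi, mag in enumerate(self.mags_):
            for contig_id in mag.member_sequences:
                for scaftig_id in contig_id.split("+"):
                    self.assignment_[scaftig_id] = mag.id
        mag_index = {m.id: i for i, m in enumerate(self.mags_)}
        self.labels_ = np.array(
            [mag_index.get(self.assignment_.get(str(s), ""), -1) for s in depths.index]
        )
        return self

    def fit_predict(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).labels_
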