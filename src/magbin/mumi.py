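"""MUM-based genome similarity (MUMi), dereplication into MAGs, and the
reconstruction rules applied after clustering.

The MUMi score between two sequence sets a and b is

    MUMi = (1 - (L_unmap_a + L_unmap_b) / (L_total_a + L_total_b)) / M,
    M    = 2 * min(L_total_a, L_total_b) / (L_total_a + L_total_b),

where L_unmap_x is the length of x not covered by any maximal unique match
(MUM intervals merged before summing).  Identical genomes score 1,
unrelated genomes 0, and full containment of the smaller genome also
scores 1 (the M term normalizes by the smaller genome).  Pairs at or above
a species-level threshold (default 0.54) are joined by single-linkage into
candidate MAGs; ungrouped sequence sets become singleton MAGs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._sequtils import (
    encode_concat,
    maximal_unique_matches,
    merged_interval_length,
    mums_concat,
)

__all__ = [
    "MumiResult", "MAG", "maximal_unique_matches", "mumi", "mumi_matrix",
    "cluster_by_mumi", "MumiClusterer", "merge_overlap", "submag_resolution",
    "finalize_mags", "assign_mag_taxonomy",
]


@dataclass
class MumiResult:
    a_id: str
    b_id: str
    L_total_a: int
    L_total_b: int
    L_unmap_a: int
    L_unmap_b: int
    M: float
    mumi: float


@dataclass
class MAG:
    """A reconstructed draft genome."""

    id: str
    provenance: str                       # singleton | combined | revised
    member_sequences: dict[str, str] = field(default_factory=dict)
    taxonomy: tuple[str, str] | None = None

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.member_sequences.values())


def mumi(
    a: list[str] | str,
    b: list[str] | str,
    min_len: int = 20,
    a_id: str = "a",
    b_id: str = "b",
) -> MumiResult:
    """MUMi similarity between two sequence sets (concatenated members).

    Members are joined with unique sentinels, so matches never span
    member boundaries and sentinel positions never count as covered.
    """
    a_seqs = [a] if isinstance(a, str) else list(a)
    b_seqs = [b] if isinstance(b, str) else list(b)
    total_a = sum(len(s) for s in a_seqs)
    total_b = sum(len(s) for s in b_seqs)
    if total_a == 0 or total_b == 0:
        raise ValueError("mumi: total lengths must be positive")
    ca, nxt = encode_concat(a_seqs)
    cb, nxt2 = encode_concat(b_seqs, start_code=nxt)
    sep = np.array([nxt2], dtype=np.int64)
    end = np.array([nxt2 + 1], dtype=np.int64)
    codes = np.concatenate([ca, sep, cb, end])
    mums = mums_concat(codes, len(ca), len(ca) + 1, min_len)
    cov_a = merged_interval_length([(s, s + L) for s, _, L in mums])
    cov_b = merged_interval_length([(s, s + L) for _, s, L in mums])
    # concatenation coordinates include sentinels, which MUMs never cover,
    # so covered length is measured against the sentinel-free totals
    unmap_a = len(ca) - cov_a - (len(ca) - total_a)
    unmap_b = len(cb) - cov_b - (len(cb) - total_b)
    M = 2.0 * min(total_a, total_b) / (total_a + total_b)
    score = (1.0 - (unmap_a + unmap_b) / (total_a + total_b)) / M
    return MumiResult(a_id, b_id, total_a, total_b, unmap_a, unmap_b, M, score)


def mumi_matrix(seq_sets: dict[str, list[str]], min_len: int = 20) -> "np.ndarray":
    """Symmetric pairwise MUMi matrix over named sequence sets."""
    ids = sorted(seq_sets)
    n = len(ids)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            r = mumi(seq_sets[ids[i]], seq_sets[ids[j]], min_len=min_len,
                     a_id=ids[i], b_id=ids[j])
            m[i, j] = m[j, i] = r.mumi
    return m


def cluster_by_mumi(
    seq_sets: dict[str, list[str]],
    threshold: float = 0.54,
    min_len: int = 20,
    precomputed: "np.ndarray | None" = None,
) -> list[list[str]]:
    """Single-linkage clusters joining pairs with MUMi >= threshold.

    Returns clusters as sorted id lists, singletons included, in
    deterministic order (by smallest member id).
    """
    ids = sorted(seq_sets)
    m = precomputed if precomputed is not None else mumi_matrix(seq_sets, min_len=min_len)
    parent = list(range(len(ids)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if m[i, j] >= threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[str]] = {}
    for i, name in enumerate(ids):
        groups.setdefault(find(i), []).append(name)
    return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])


class MumiClusterer:
    """Dereplicate qualified SLGs into candidate MAG clusters by MUMi.

    Parameters
    ----------
    threshold : float, default=0.54
        Species-level MUMi similarity for joining two SLGs.
    min_mum : int, default=20
        Minimum MUM length in bp.

    Attributes
    ----------
    ids_ : sorted sequence-set ids
    mumi_matrix_ : symmetric pairwise MUMi array over ``ids_``
    clusters_ : list of id lists (singletons included)
    labels_ : cluster index per id in ``ids_`` order
    """

    def __init__(self, threshold: float = 0.54, min_mum: int = 20):
        self.threshold = threshold
        self.min_mum = min_mum

    def get_params(self, deep=True):
        return {"threshold": self.threshold, "min_mum": self.min_mum}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, seq_sets: dict[str, list[str]], y=None):
        self.ids_ = sorted(seq_sets)
        self.mumi_matrix_ = mumi_matrix(seq_sets, min_len=self.min_mum)
        self.clusters_ = cluster_by_mumi(seq_sets, threshold=self.threshold,
                                         precomputed=self.mumi_matrix_)
        assign = {name: ci for ci, c in enumerate(self.clusters_) for name in c}
        self.labels_ = np.array([assign[i] for i in self.ids_])
        return self

    def fit_predict(self, seq_sets, y=None):
        return self.fit(seq_sets).labels_


def merge_overlap(sequences: dict[str, str], min_overlap: int = 500) -> dict[str, str]:
    """Greedy exact suffix-prefix merging of sequences.

    Repeatedly merges the pair with the longest exact suffix->prefix
    overlap >= ``min_overlap`` (ties broken by lexicographic id pair);
    shorter overlaps are treated as unreliable and left unmerged.  Merged
    sequences keep a composite id ``left+right``.
    """
    if not sequences:
        raise ValueError("merge_overlap: empty input")
    seqs = dict(sequences)

    def best_pair():
        best = None
        for ida, sa in seqs.items():
            for idb, sb in seqs.items():
                if ida == idb:
                    continue
                limit = min(len(sa), len(sb))
                for k in range(limit, min_overlap - 1, -1):
                    if sa[-k:] == sb[:k]:
                        key = (-k, ida, idb)
                        if best is None or key < best[0]:
                            best = (key, ida, idb, k)
                        break
        return best

    while len(seqs) > 1:
        hit = best_pair()
        if hit is None:
            break
        _, ida, idb, k = hit
        merged = seqs[ida] + seqs[idb][k:]
        del seqs[ida], seqs[idb]
        seqs[f"{ida}+{idb}"] = merged
    return seqs


def submag_resolution(
    sub_mags: list[tuple[str, str, set[str]]],
    original_slgs: dict[str, "object"],
    scaftig_lengths: dict[str, int],
    min_coverage: float = 0.90,
) -> list[MAG]:
    """Resolve split candidate MAGs against their original SLGs.

    ``sub_mags``: (sub_mag_id, original_slg_id, member scaftig ids).
    A sub-MAG retaining >= ``min_coverage`` of its original SLG's sequence
    (by bp) is kept as a revised MAG; otherwise the original SLG itself is
    emitted (once) as the revised MAG.
    """
    out: list[MAG] = []
    replaced: set[str] = set()
    for sub_id, slg_id, member_ids in sub_mags:
        if slg_id not in original_slgs:
            raise KeyError(f"submag_resolution: unknown original SLG {slg_id!r}")
        slg = original_slgs[slg_id]
        slg_total = sum(scaftig_lengths[m] for m in slg.members)
        shared = sum(scaftig_lengths[m] for m in member_ids if m in slg.members)
        if slg_total > 0 and shared / slg_total >= min_coverage:
            out.append(MAG(id=sub_id, provenance="revised",
                           member_sequences={m: slg.sequences.get(m, "") for m in member_ids}))
        elif slg_id not in replaced:
            replaced.add(slg_id)
            out.append(MAG(id=f"{slg_id}.revised", provenance="revised",
                           member_sequences={m: slg.sequences.get(m, "") for m in slg.members}))
    return out


def finalize_mags(mags: list[MAG], min_size: int = 1_000_000) -> list[MAG]:
    """Keep MAGs with total length strictly greater than ``min_size``."""
    return [m for m in mags if m.total_length > min_size]


def assign_mag_taxonomy(gene_labels: list[str | None]) -> str | None:
    """Majority-rule taxonomy over a MAG's genes at one rank.

    Returns the name carried by strictly more than half of ALL genes
    (unassigned genes count in the denominator), else None.
    """
    if not gene_labels:
        raise ValueError("assign_mag_taxonomy: empty gene list")
    counts: dict[str, int] = {}
    for lab in gene_labels:
        if lab is not None:
            counts[lab] = counts.get(lab, 0) + 1
    n = len(gene_labels)
    for name, c in counts.items():
        if c > n / 2:
            return name
    return None
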