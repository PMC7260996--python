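"""Abundance profiles: length-normalized relative abundance, mapping ratio,
coverage-based depth zeroing, and MAG abundance aggregation.

Relative abundance follows the standard gene-catalog normalization: counts
are divided by sequence length and renormalized to sum to 1 per sample.
Multi-mapped read handling is out of scope (profiles are consumed as
correlations downstream, which are invariant to the per-sample scale).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def relative_abundance(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Length-normalized relative abundance.

    ``a[i, s] = (c[i, s] / L_i) / sum_j (c[j, s] / L_j)``; columns with
    all-zero counts stay all-zero.
    """
    missing = counts.index.difference(lengths.index)
    if len(missing) > 0:
        raise KeyError(f"relative_abundance: no length for row id(s) {list(missing[:5])}")
    L = lengths.loc[counts.index].astype(float)
    if (L <= 0).any():
        raise ValueError("relative_abundance: lengths must be positive")
    if (counts.to_numpy() < 0).any():
        raise ValueError("relative_abundance: negative counts")
    rate = counts.div(L, axis=0)
    col_sum = rate.sum(axis=0)
    col_sum = col_sum.where(col_sum > 0, 1.0)
    return rate.div(col_sum, axis=1)


def mapping_ratio(mapped: int, total: int) -> float:
    """Fraction of reads mapped: mapped / total."""
    if total <= 0:
        raise ValueError("mapping_ratio: total reads must be positive")
    if not 0 <= mapped <= total:
        raise ValueError("mapping_ratio: mapped must lie in [0, total]")
    return mapped / total


def zero_low_coverage(
    depths: pd.DataFrame, coverage: pd.DataFrame, cutoff: float = 0.1
) -> pd.DataFrame:
    """Zero depth entries whose breadth of coverage is below ``cutoff``.

    Low-coverage depth signal is alignment noise; entries with coverage
    strictly less than the cutoff are set to 0, everything else is
    unchanged.  Idempotent.
    """
    if coverage is None:
        raise ValueError("zero_low_coverage: coverage matrix required")
    if coverage.shape != depths.shape:
        raise ValueError("zero_low_coverage: depth and coverage shapes differ")
    cov = coverage.to_numpy()
    if ((cov < 0) | (cov > 1)).any():
        raise ValueError("zero_low_coverage: coverage outside [0, 1]")
    out = depths.copy()
    out[coverage.reindex_like(depths) < cutoff] = 0.0
    return out


def mag_abundance(gene_abundance: pd.DataFrame, gene_to_mag: dict[str, str]) -> pd.DataFrame:
    """Per-sample MAG abundance: sum of its member genes' abundances.

    Genes absent from the association are ignored; an association entry
    referencing an unknown gene raises.
    """
    unknown = set(gene_to_mag) - set(gene_abundance.index)
    if unknown:
        raise KeyError(f"mag_abundance: unknown gene id(s) {sorted(unknown)[:5]}")
    if not gene_to_mag:
        return pd.DataFrame(columns=gene_abundance.columns)
    membership = pd.Series(gene_to_mag, name="mag")
    sub = gene_abundance.loc[membership.index]
    out = sub.groupby(membership).sum()
    out.index.name = None
    return out
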