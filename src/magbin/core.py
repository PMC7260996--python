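"""Total and minimal (core) metagenome characterization.

Given per-sample feature abundances (genes, KOs, CAZy families), this
module computes presence calls at an abundance cutoff, total/shared
feature curves over random sub-cohorts, shared-by-fraction summaries, the
KO second-level functional contribution statistic with its permutation
test, and the basic diversity indices (richness, Shannon, Whittaker beta).

The contribution of second-level function j in a KO set of size N is

    p_ij = f_ij / sum_j f_ij        (per-KO share of its functions)
    P_j  = sum_i p_ij / N           (mean share over the KO set)

where f_ij indicates whether KO i carries function j.  Enrichment or
depletion of each function in a minimal (core) KO set relative to the
total annotated set is scored by re-drawing sets of the same size without
replacement (default 999 draws) and reading off the empirical tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import entropy

DEFAULT_PRESENCE_CUTOFF = 1e-7


def presence(table: pd.DataFrame, cutoff: float = DEFAULT_PRESENCE_CUTOFF) -> pd.DataFrame:
    """Boolean presence calls: abundance strictly greater than ``cutoff``."""
    if cutoff < 0:
        raise ValueError("presence: cutoff must be >= 0")
    return table > cutoff


@dataclass
class CoreCurve:
    """Shared/total feature counts over random sub-cohorts of size n."""

    draws: pd.DataFrame  # columns: n, replicate, shared, total

    def summary(self) -> pd.DataFrame:
        g = self.draws.groupby("n")[["shared", "total"]]
        out = g.mean()
        out.columns = ["shared_mean", "total_mean"]
        q = g.quantile([0.025, 0.975]).unstack()
        out["shared_lo"], out["shared_hi"] = q[("shared", 0.025)], q[("shared", 0.975)]
        out["total_lo"], out["total_hi"] = q[("total", 0.025)], q[("total", 0.975)]
        return out


def core_curve(
    pres: pd.DataFrame,
    n_values,
    replicates: int = 100,
    seed: int | None = None,
) -> CoreCurve:
    """Shared and total feature counts in random combinations of n samples.

    For each n, ``replicates`` sub-cohorts are drawn without replacement;
    shared = features present in all n members, total = present in at
    least one.  When ``replicates`` covers all C(S, n) combinations, every
    combination is enumerated exactly once instead of sampled.
    """
    S = pres.shape[1]
    n_values = list(n_values)
    if any(n < 1 or n > S for n in n_values):
        raise ValueError(f"core_curve: n must lie in [1, {S}]")
    rng = np.random.default_rng(seed)
    P = pres.to_numpy(dtype=bool)
    rows = []
    for n in n_values:
        n_comb = math.comb(S, n)
        if replicates >= n_comb:
            combos = list(combinations(range(S), n))
        else:
            combos = [rng.choice(S, size=n, replace=False) for _ in range(replicates)]
        for rep, cols in enumerate(combos):
            sub = P[:, list(cols)]
            rows.append((n, rep, int(sub.all(axis=1).sum()), int(sub.any(axis=1).sum())))
    return CoreCurve(pd.DataFrame(rows, columns=["n", "replicate", "shared", "total"]))


def shared_by_fraction(pres: pd.DataFrame, fractions) -> dict[float, int]:
    """Features present in at least ceil(fraction * n_samples) samples."""
    S = pres.shape[1]
    out = {}
    for f in fractions:
        if not 0 < f <= 1:
            raise ValueError("shared_by_fraction: fractions must lie in (0, 1]")
        k = math.ceil(f * S)
        out[f] = int((pres.sum(axis=1) >= k).sum()) if S else 0
    return out


def _contribution_matrix(kos: list[str], hierarchy: dict[str, set]) -> tuple[np.ndarray, list[str]]:
    """Rows of p_ij for the given KOs; columns = sorted function universe."""
    funcs = sorted(set().union(*(hierarchy[k] for k in kos)))
    fi = {f: j for j, f in enumerate(funcs)}
    P = np.zeros((len(kos), len(funcs)))
    for i, ko in enumerate(kos):
        fs = hierarchy[ko]
        if not fs:
            raise ValueError(f"ko_contribution: KO {ko!r} has no functions")
        for f in fs:
            P[i, fi[f]] = 1.0 / len(fs)
    return P, funcs


def ko_contribution(ko_set, hierarchy: dict[str, set]) -> dict[str, float]:
    """Relative contribution P_j of each second-level function in a KO set."""
    kos = sorted(ko_set)
    if not kos:
        raise ValueError("ko_contribution: empty KO set")
    missing = [k for k in kos if k not in hierarchy]
    if missing:
        raise KeyError(f"ko_contribution: KO(s) not in hierarchy: {missing[:5]}")
    P, funcs = _contribution_matrix(kos, hierarchy)
    return dict(zip(funcs, P.mean(axis=0)))


def permutation_enrichment(
    minimal_set,
    all_set,
    hierarchy: dict[str, set],
    n_perm: int = 999,
    alpha: float = 0.01,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutation test for function enrichment in the minimal KO set.

    Draws ``n_perm`` same-size KO sets from ``all_set`` without
    replacement, recomputes P_j for each, and reports per function the
    empirical one-sided tails with the +1 correction:

        p_enriched = (1 + #{P_perm >= P_obs}) / (n_perm + 1)

    (symmetrically with <= for depletion).  The smaller tail and its
    direction are reported; significant iff p < ``alpha``.
    """
    minimal = sorted(set(minimal_set))
    universe = sorted(set(all_set))
    if not minimal:
        raise ValueError("permutation_enrichment: empty minimal set")
    if not set(minimal) <= set(universe):
        raise ValueError("permutation_enrichment: minimal set not within all set")
    rng = np.random.default_rng(seed)
    P, funcs = _contribution_matrix(universe, hierarchy)
    pos = {k: i for i, k in enumerate(universe)}
    obs = P[[pos[k] for k in minimal]].mean(axis=0)
    k = len(minimal)
    if k == len(universe):
        perm_means = np.tile(obs, (n_perm, 1))
    else:
        u = rng.random((n_perm, len(universe)))
        idx = np.argpartition(u, k - 1, axis=1)[:, :k]
        perm_means = P[idx].mean(axis=1)
    tol = 1e-12
    n_ge = (perm_means >= obs - tol).sum(axis=0)
    n_le = (perm_means <= obs + tol).sum(axis=0)
    p_enr = (1.0 + n_ge) / (n_perm + 1.0)
    p_dep = (1.0 + n_le) / (n_perm + 1.0)
    direction = np.where(p_enr <= p_dep, "enriched", "depleted")
    p = np.minimum(p_enr, p_dep)
    return pd.DataFrame(
        {
            "function": funcs,
            "observed_P": obs,
            "mean_null_P": perm_means.mean(axis=0),
            "direction": direction,
            "p_value": p,
            "significant": p < alpha,
        }
    ).set_index("function")


def richness(pres_col: pd.Series) -> int:
    """Number of present features in one sample."""
    if len(pres_col) == 0:
        raise ValueError("richness: empty column")
    return int(pres_col.sum())


def shannon(abundance_col: pd.Series) -> float:
    """Shannon index -sum(p ln p) over present features (natural log)."""
    p = np.asarray(abundance_col, dtype=float)
    p = p[p > 0]
    if p.size == 0:
        raise ValueError("shannon: undefined for an all-absent sample")
    return float(entropy(p / p.sum()))


def whittaker_beta(pres_a: pd.Series, pres_b: pd.Series, variant: str = "excess") -> float:
    """Whittaker beta diversity for a pair of samples.

    ``excess`` (default): gamma / mean(alpha) - 1, zero for identical
    samples; ``ratio``: gamma / mean(alpha).
    """
    a = np.asarray(pres_a, dtype=bool)
    b = np.asarray(pres_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("whittaker_beta: mismatched samples")
    gamma = float((a | b).sum())
    alpha_bar = (a.sum() + b.sum()) / 2.0
    if alpha_bar == 0:
        raise ValueError("whittaker_beta: undefined for two empty samples")
    ratio = gamma / alpha_bar
    if variant == "excess":
        return ratio - 1.0
    if variant == "ratio":
        return ratio
    raise ValueError(f"whittaker_beta: unknown variant {variant!r}")
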