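"""Total/minimal metagenome statistics: presence calls, core curves, the
KO contribution formula, permutation enrichment and diversity indices."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magbin import (
    core_curve,
    ko_contribution,
    permutation_enrichment,
    presence,
    richness,
    shannon,
    shared_by_fraction,
    whittaker_beta,
)


class TestPresence:
    def test_cutoff_is_strict(self):
        t = pd.DataFrame({"s": [1e-7, 2e-7, 0.0]}, index=["a", "b", "c"])
        p = presence(t, cutoff=1e-7)
        assert p["s"].tolist() == [False, True, False]

    def test_zero_cutoff_keeps_zero_absent(self):
        t = pd.DataFrame({"s": [0.0]})
        assert not presence(t, cutoff=0.0).iloc[0, 0]


class TestCoreCurve:
    def _worked_example(self):
        # samples with feature sets {f1,f2,f3}, {f1,f2}, {f1}
        return pd.DataFrame(
            {"s1": [1, 1, 1], "s2": [1, 1, 0], "s3": [1, 0, 0]},
            index=["f1", "f2", "f3"],
        ).astype(bool)

    def test_exhaustive_pair_means(self):
        """All 3 pairs enumerated: mean shared 4/3, mean total 8/3."""
        curve = core_curve(self._worked_example(), [2], replicates=100, seed=0)
        d = curve.draws
        assert len(d) == 3  # exhaustive, not 100 resamples
        assert d["shared"].mean() == pytest.approx(4 / 3)
        assert d["total"].mean() == pytest.approx(8 / 3)

    def test_identical_samples_shared_equals_total(self):
        p = pd.DataFrame(np.ones((5, 4), dtype=bool))
        curve = core_curve(p, [1, 2, 3, 4], replicates=50, seed=0)
        assert (curve.draws["shared"] == 5).all() and (curve.draws["total"] == 5).all()

    def test_monotonicity_under_exhaustive_enumeration(self, rng):
        p = pd.DataFrame(rng.random((30, 5)) < 0.6)
        curve = core_curve(p, [1, 2, 3, 4, 5], replicates=10_000, seed=0)
        m = curve.draws.groupby("n")[["shared", "total"]].mean()
        assert (m["shared"].diff().dropna() <= 1e-12).all()
        assert (m["total"].diff().dropna() >= -1e-12).all()

    def test_n_larger_than_cohort_errors(self):
        with pytest.raises(ValueError):
            core_curve(self._worked_example(), [4])


class TestSharedByFraction:
    def test_full_core_and_ceiling(self):
        p = pd.DataFrame(
            {"s1": [1, 1, 1], "s2": [1, 1, 0], "s3": [1, 0, 0]}, dtype=bool
        )
        out = shared_by_fraction(p, [0.5, 0.9, 1.0])
        # thresholds: ceil(1.5)=2, ceil(2.7)=3, 3 samples
        assert out == {0.5: 2, 0.9: 1, 1.0: 1}

    def test_empty_table(self):
        p = pd.DataFrame(dtype=bool)
        assert shared_by_fraction(p, [1.0]) == {1.0: 0}

    def test_fraction_one_matches_full_cohort_core(self, rng):
        p = pd.DataFrame(rng.random((40, 6)) < 0.5)
        curve = core_curve(p, [6], replicates=1, seed=0)
        assert shared_by_fraction(p, [1.0])[1.0] == curve.draws["shared"].iloc[0]


class TestKoContribution:
    def test_single_ko_single_function(self):
        assert ko_contribution({"K1"}, {"K1": {"A"}}) == {"A": 1.0}

    def test_two_ko_worked_example(self):
        P = ko_contribution({"K1", "K2"}, {"K1": {"A"}, "K2": {"A", "B"}})
        assert P["A"] == pytest.approx(0.75) and P["B"] == pytest.approx(0.25)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10**6), n=st.integers(1, 30))
    def test_contributions_sum_to_one(self, seed, n):
        rng = np.random.default_rng(seed)
        funcs = [f"F{i}" for i in range(8)]
        hier = {
            f"K{i}": set(rng.choice(funcs, size=int(rng.integers(1, 4)), replace=False))
            for i in range(n)
        }
        P = ko_contribution(set(hier), hier)
        assert sum(P.values()) == pytest.approx(1.0)

    def test_ko_without_functions_errors(self):
        with pytest.raises((ValueError, KeyError)):
            ko_contribution({"K1"}, {"K1": set()})


class TestPermutationEnrichment:
    def _hier(self, rng, n_kos=60, n_funcs=6):
        funcs = [f"F{i}" for i in range(n_funcs)]
        return {
            f"K{i}": set(rng.choice(funcs, size=int(rng.integers(1, 3)), replace=False))
            for i in range(n_kos)
        }

    def test_degenerate_full_set_gives_p_one(self, rng):
        hier = self._hier(rng)
        res = permutation_enrichment(set(hier), set(hier), hier, n_perm=99, seed=0)
        assert (res["p_value"] == 1.0).all()
        assert not res["significant"].any()

    def test_extreme_enrichment_hits_minimum_p(self, rng):
        hier = {f"K{i}": {"A"} for i in range(20)} | {f"J{i}": {"B"} for i in range(180)}
        minimal = {f"K{i}" for i in range(20)}
        res = permutation_enrichment(minimal, set(hier), hier, n_perm=999, seed=1)
        assert res.at["A", "direction"] == "enriched"
        assert res.at["A", "p_value"] == pytest.approx(1 / 1000)

    def test_minimal_must_be_subset(self, rng):
        hier = self._hier(rng)
        with pytest.raises(ValueError, match="not within"):
            permutation_enrichment({"K0", "ZZZ"}, set(hier), hier | {"ZZZ": {"A"}})

    def test_null_p_values_super_uniform(self, rng):
        """Empirical CDF of null p-values never exceeds the uniform CDF
        beyond Monte-Carlo slack (Kolmogorov-Smirnov style bound)."""
        hier = self._hier(rng, n_kos=80)
        kos = sorted(hier)
        pvals = []
        for t in range(200):
            minimal = list(rng.choice(kos, size=20, replace=False))
            res = permutation_enrichment(minimal, kos, hier, n_perm=199,
                                         seed=int(rng.integers(2**31)))
            pvals.extend(res["p_value"].tolist())
        pvals = np.sort(pvals)
        grid = np.linspace(0.01, 1.0, 50)
        ecdf = np.searchsorted(pvals, grid, side="right") / len(pvals)
        # two-sided min-tail p-values: ecdf(t) <= 2t + KS slack
        slack = 3.0 / np.sqrt(len(pvals))
        assert (ecdf <= 2 * grid + slack).all()


class TestDiversity:
    def test_shannon_uniform_is_log_k(self):
        col = pd.Series([0.25] * 4)
        assert shannon(col) == pytest.approx(math.log(4))

    def test_shannon_single_feature_zero(self):
        assert shannon(pd.Series([1.0, 0.0])) == 0.0

    def test_shannon_all_absent_flagged(self):
        with pytest.raises(ValueError):
            shannon(pd.Series([0.0, 0.0]))

    def test_richness(self):
        assert richness(pd.Series([True, False, True])) == 2
        with pytest.raises(ValueError):
            richness(pd.Series([], dtype=bool))

    def test_whittaker_identical_samples_zero(self):
        a = pd.Series([True, True, False])
        assert whittaker_beta(a, a) == 0.0

    def test_whittaker_disjoint_samples(self):
        a = pd.Series([True, True, False, False])
        b = pd.Series([False, False, True, True])
        assert whittaker_beta(a, b) == pytest.approx(1.0)   # gamma=4, alpha_bar=2
        assert whittaker_beta(a, b, variant="ratio") == pytest.approx(2.0)
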