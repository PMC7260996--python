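"""MUM detection, the MUMi similarity formula, dereplication clustering,
overlap merging and the MAG reconstruction rules."""

import numpy as np
import pytest

from magbin import (
    GenomeSpec,
    assign_mag_taxonomy,
    cluster_by_mumi,
    finalize_mags,
    maximal_unique_matches,
    merge_overlap,
    mumi,
    simulate_genomes,
    submag_resolution,
)
from magbin.binning import SLG
from magbin.mumi import MAG, MumiClusterer

from ._oracles import mum_oracle, random_dna


class TestMaximalUniqueMatches:
    def test_identical_nonrepetitive_strings_give_one_full_mum(self, rng):
        a = random_dna(rng, 100)
        assert maximal_unique_matches(a, a, 20) == [(0, 0, 100)]

    def test_unrelated_strings_share_nothing_long(self, rng):
        """P(30 bp collision) is astronomically small for random DNA."""
        for _ in range(20):
            a, b = random_dna(rng, 100), random_dna(rng, 100)
            assert maximal_unique_matches(a, b, 30) == []

    def test_small_worked_example(self):
        # single shared maximal substring "ACCC" at a[2:], b[2:]
        assert maximal_unique_matches("AAACCC", "TTACCC", 3) == [(2, 2, 4)]

    def test_repeated_substring_is_not_unique(self):
        # "ACGTACGT" contains the 4-mer ACGT twice -> not a MUM of length 4
        got = maximal_unique_matches("ACGTACGT", "TTTTACGTTTTT", 4)
        assert (0, 4, 4) not in got and (4, 4, 4) not in got

    @pytest.mark.parametrize("min_len", [10, 20])
    def test_matches_brute_force_oracle(self, rng, min_len):
        """Exact set equality with diagonal-enumeration oracle."""
        for trial in range(15):
            la, lb = rng.integers(50, 800, 2)
            a, b = random_dna(rng, la), random_dna(rng, lb)
            if trial % 2:  # plant a shared segment so matches exist
                seg = a[5 : 5 + 60]
                b = b[:10] + seg + b[10:]
            assert set(maximal_unique_matches(a, b, min_len)) == mum_oracle(a, b, min_len)


class TestMumi:
    def test_identity_scores_one(self, rng):
        a = random_dna(rng, 1000)
        r = mumi(a, a)
        assert r.mumi == pytest.approx(1.0, abs=1e-9)
        assert r.L_unmap_a == 0 and r.M == 1.0

    def test_unrelated_scores_zero(self, rng):
        assert mumi(random_dna(rng, 1000), random_dna(rng, 1000)).mumi == 0.0

    def test_containment_scores_one(self, rng):
        """1 kb genome inside a 2 kb genome: M cancels the size imbalance."""
        a = random_dna(rng, 1000)
        b = a + random_dna(rng, 1000)
        r = mumi(a, b)
        assert r.L_unmap_a == 0 and r.L_unmap_b == 1000
        assert r.M == pytest.approx(2 / 3)
        assert r.mumi == pytest.approx(1.0, abs=1e-9)

    def test_symmetry(self, rng):
        a, b = random_dna(rng, 600), random_dna(rng, 900)
        b = b[:200] + a[100:400] + b[200:]
        assert mumi(a, b).mumi == pytest.approx(mumi(b, a).mumi, abs=1e-12)

    def test_multi_member_sets_do_not_match_across_boundaries(self, rng):
        # two halves of one member of a must not chain into b through the join
        a1, a2 = random_dna(rng, 300), random_dna(rng, 300)
        r = mumi([a1, a2], [a1 + a2])
        assert r.L_unmap_a == 0
        assert r.mumi == pytest.approx(1.0, abs=1e-9)


class TestClusterByMumi:
    def test_single_linkage_on_three_sets(self, rng):
        a = random_dna(rng, 800)
        b = a[:700] + random_dna(rng, 100)     # similar to a
        c = random_dna(rng, 800)               # unrelated
        clusters = cluster_by_mumi({"a": [a], "b": [b], "c": [c]}, threshold=0.54)
        assert clusters == [["a", "b"], ["c"]]

    def test_all_below_threshold_all_singletons(self, rng):
        sets = {f"g{i}": [random_dna(rng, 500)] for i in range(4)}
        assert cluster_by_mumi(sets) == [["g0"], ["g1"], ["g2"], ["g3"]]

    def test_strains_at_one_percent_divergence_cluster(self):
        specs = [
            GenomeSpec(id="g1", length=20_000, gc_target=0.5),
            GenomeSpec(id="g2", copy_of="g1", divergence=0.01),
        ]
        seqs = dict(simulate_genomes(specs, seed=4))
        clusterer = MumiClusterer(threshold=0.54).fit({k: [v] for k, v in seqs.items()})
        assert clusterer.clusters_ == [["g1", "g2"]]
        assert clusterer.mumi_matrix_[0, 1] > 0.54


class TestMergeOverlap:
    def test_merge_at_exact_overlap(self):
        out = merge_overlap({"a": "ACGTACGT", "b": "ACGTTTTT"}, min_overlap=4)
        assert list(out.values()) == ["ACGTACGTTTTT"]

    def test_short_overlap_left_unmerged(self):
        out = merge_overlap({"a": "ACGTACGT", "b": "ACGTTTTT"}, min_overlap=5)
        assert sorted(out.values()) == ["ACGTACGT", "ACGTTTTT"]

    def test_single_sequence_unchanged(self):
        assert merge_overlap({"a": "ACGT"}, min_overlap=4) == {"a": "ACGT"}

    def test_chain_of_three(self, rng):
        g = random_dna(rng, 1500)
        parts = {"p1": g[:700], "p2": g[400:1100], "p3": g[800:]}
        out = merge_overlap(parts, min_overlap=300)
        assert list(out.values()) == [g]


class TestSubmagResolution:
    def _slg(self, n_scaftigs=10, bp=100):
        members = {f"s{i}" for i in range(n_scaftigs)}
        return SLG(id="slg_a", members=members, total_length=n_scaftigs * bp, n50=bp,
                   sequences={m: "A" * bp for m in members})

    def test_high_coverage_submag_retained(self):
        slg = self._slg()
        lengths = {m: 100 for m in slg.members} | {"s9x": 100}
        sub = [("sub1", "slg_a", {f"s{i}" for i in range(9)} | {"s9x"})]  # 900/1000
        out = submag_resolution(sub, {"slg_a": slg}, lengths)
        assert out[0].id == "sub1" and out[0].provenance == "revised"

    def test_low_coverage_replaced_by_original_slg_once(self):
        slg = self._slg()
        lengths = {m: 100 for m in slg.members}
        subs = [
            ("sub1", "slg_a", {f"s{i}" for i in range(8)}),   # 800/1000 < 0.9
            ("sub2", "slg_a", {"s8", "s9"}),                  # also fails
        ]
        out = submag_resolution(subs, {"slg_a": slg}, lengths)
        assert len(out) == 1 and out[0].id == "slg_a.revised"
        assert set(out[0].member_sequences) == slg.members

    def test_identity_coverage_retained(self):
        slg = self._slg()
        out = submag_resolution([("sub1", "slg_a", set(slg.members))], {"slg_a": slg},
                                {m: 100 for m in slg.members})
        assert out[0].id == "sub1"

    def test_dangling_link_errors(self):
        with pytest.raises(KeyError):
            submag_resolution([("sub1", "missing", {"s0"})], {}, {})


class TestFinalizeAndTaxonomy:
    def test_strict_size_boundary(self):
        exactly = MAG(id="m1", provenance="singleton", member_sequences={"c": "A" * 1000})
        above = MAG(id="m2", provenance="singleton", member_sequences={"c": "A" * 1001})
        out = finalize_mags([exactly, above], min_size=1000)
        assert [m.id for m in out] == ["m2"]
        assert finalize_mags([], min_size=10) == []

    @pytest.mark.parametrize(
        "labels, expected",
        [
            (["Prevotella"] * 6 + [None] * 4, "Prevotella"),
            (["Prevotella"] * 5 + [None] * 5, None),
            (["Prevotella"] * 4 + ["Butyrivibrio"] * 4 + [None] * 2, None),
        ],
    )
    def test_majority_rule_counts_unassigned_genes(self, labels, expected):
        assert assign_mag_taxonomy(labels) == expected
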