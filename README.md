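# magbin

Co-abundance binning of metagenome scaftigs into metagenome-assembled
genomes (MAGs), with MUM-based dereplication and total/minimal-metagenome
statistics — the computational core of deep-cohort rumen (or any gut)
metagenomics studies, packaged as tested, reusable scikit-learn-style
estimators.

## Who this is for

Microbiome researchers who have assembled scaftigs (contiguous, gap-free
sequences) from many samples and want to recover draft genomes without
cultivation, then characterize which genes and functions a cohort shares.
Everything is driven by a ground-truthed synthetic-community generator, so
every stage of the pipeline can be validated against known genome
assignments rather than marker-gene heuristics.

## The method

**1. Scaftig-linkage groups (SLGs).** Scaftigs from one genome rise and
fall together across samples. An edge joins two scaftigs when the Pearson
correlation of their depth profiles exceeds *r* = 0.7; groups are merged
greedily while the inter-group edge density (realized / possible cross
edges) stays ≥ 0.99; groups longer than 1 Mb become preliminary SLGs.

**2. GC × depth refinement.** Each SLG is inspected in the plane of
scaftig GC content versus mean aligned depth with DBSCAN
(ε = 0.10, MinPts = 49 at genome scale). A single cluster → *qualified*;
scattered points → discarded; ≥ 2 clusters → discarded as too fragmented
when scaftig N50 < 2,000 bp, otherwise split into per-cluster children,
each retained only at coverage depth > 20×.

**3. MUMi dereplication.** For qualified SLGs *a*, *b* with total lengths
L and unmatched lengths L_unmap (positions not covered by any maximal
unique match, MUM ≥ 20 bp):

    MUMi = (1 − (L_unmap_a + L_unmap_b) / (L_a + L_b)) / M,
    M    = 2·min(L_a, L_b) / (L_a + L_b)

Identical genomes score 1, unrelated genomes 0, containment of the smaller
genome 1. Single-linkage clustering at MUMi ≥ 0.54 (a species-level
threshold) groups SLGs; singletons become singleton MAGs, clusters are
merged (exact scaftig overlaps ≥ 500 bp; shorter overlaps are unreliable
and left unmerged), re-examined in GC × depth space, split candidates are
resolved against their original SLGs (a sub-MAG must retain ≥ 90% of its
SLG's sequence, else the SLG itself stands), and only MAGs > 1 Mb are
emitted. A MAG is taxonomically labelled when > 50% of all its genes
(unassigned included in the denominator) agree at a rank.

**Core-metagenome statistics.** Presence = relative abundance > 1 × 10⁻⁷;
shared/total feature counts over random sub-cohorts of size *n*;
contribution of second-level function *j* in a KO set of size *N*:
p_ij = f_ij / Σ_j f_ij, P_j = Σ_i p_ij / N; enrichment/depletion of the
minimal (all-samples) KO set scored against 999 same-size random draws
from the total set (significant at *P* < 0.01); richness, Shannon and
Whittaker β diversity.

## Worked example

```python
from magbin import GenomeSpec, MagPipeline, evaluate_bins, simulate_community

# 8 genomes x 50 kb with distinct GC, 24 samples, depth noise CV 0.1
specs = [GenomeSpec(id=f"g{i+1}", length=50_000, gc_target=0.3 + 0.4 * i / 7)
         for i in range(8)]
truth, depths, coverage = simulate_community(specs, n_samples=24, seed=1, noise_cv=0.1)

pipe = MagPipeline(slg_min_length=25_000, min_pts=5, n50_min=800, mag_min_size=25_000)
pipe.fit(depths, sequences={s.id: s.sequence for s in truth.scaftigs}, coverage=coverage)

ev = evaluate_bins(pipe.assignment_, truth)
print(f"{len(truth.scaftigs)} scaftigs -> {len(pipe.slgs_)} SLGs -> "
      f"{len(pipe.qualified_)} qualified -> {len(pipe.mags_)} MAGs")
print(f"ARI {ev.ari:.3f} | median completeness {ev.median_completeness:.1%} | "
      f"max contamination {ev.max_contamination:.1%}")
```

prints

```
315 scaftigs -> 8 SLGs -> 8 qualified -> 8 MAGs
ARI 0.993 | median completeness 98.6% | max contamination 2.7%
```

i.e. the pipeline recovers one MAG per simulated genome; the adjusted Rand
index compares the scaftig→MAG partition with the true scaftig→genome
partition, and completeness/contamination are measured in base pairs
against the known genomes (length thresholds here are scaled to the 50 kb
synthetic genomes; at real genome scale use the 1 Mb defaults).

The same pipeline is available from the shell:

```bash
magbin simulate --n-genomes 8 --n-samples 24 --seed 1 --out community/
magbin cluster-mags --depths community/depths.tsv --fasta community/scaftigs.fasta \
    --coverage community/coverage.tsv --slg-min-length 25000 --min-pts 5 \
    --n50-min 800 --min-size 25000 --out-dir mags/
```

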