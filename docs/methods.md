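# Methods

## Model and assumptions

The pipeline recovers draft genomes from multi-sample metagenome
assemblies using three signals that are independent of reference
databases:

1. **Co-abundance.** Fragments of one genome share a depth profile across
   samples up to multiplicative noise, so their pairwise Pearson
   correlation is high; fragments of different genomes correlate only by
   chance. This holds when genome abundances vary substantially between
   samples (the generator draws them log-normal with ~1 decade of spread)
   and fails for genomes whose abundances co-vary across the entire
   cohort (e.g. obligate symbionts) — such genomes can merge into one SLG
   and must be separated downstream.
2. **Composition × depth coherence.** Within a correctly binned group,
   scaftig GC content and mean depth form one tight cluster; chimeric
   groups form several; spurious groups scatter.
3. **Sequence identity.** The same species assembled from different
   samples yields sequence sets whose maximal unique matches (MUMs) cover
   most of the smaller set; the MUMi score normalizes this coverage so
   that identity and containment both score 1.

The method assumes substitution-level divergence between strains of a
species (the MUMi stage tolerates ~1% divergence comfortably at a minimum
MUM length of 20 bp) and assumes scaftigs are long enough (≥ 500 bp) that
depth estimates are stable.

## Parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| `r_threshold` | 0.7 | Pearson correlation above which two scaftigs are linked |
| `density_min` | 0.99 | minimum realized/possible cross-edge fraction for a merge |
| `slg_min_length` | 1,000,000 bp | minimum total length (strict >) of a preliminary SLG |
| `eps`, `min_pts` | 0.10, 49 | DBSCAN radius in the scaled GC×depth plane; core-point threshold (self included) |
| `noise_max` | 0.5 | noise fraction above which a one-cluster SLG is still discarded as scattered |
| `n50_min` | 2,000 bp | multi-cluster SLGs below this scaftig N50 are too fragmented to split |
| `depth_min` | 20× | length-weighted mean depth a split child needs to survive |
| `mumi_threshold` | 0.54 | species-level MUMi similarity for single-linkage joins |
| `min_mum` | 20 bp | minimum MUM length (standard genome-comparison convention) |
| `min_overlap` | 500 bp | exact scaftig overlaps shorter than this are unreliable and not merged |
| `submag_coverage` | 0.90 | fraction of its original SLG a sub-MAG must retain |
| `mag_min_size` | 1,000,000 bp | final MAG size filter (strict >) |
| `coverage_cutoff` | 0.1 | depth entries with breadth of coverage below this are zeroed |
| presence cutoff | 1 × 10⁻⁷ | relative abundance strictly above this counts as present |
| `n_perm`, `alpha` | 999, 0.01 | permutation draws and significance level for enrichment |

`min_pts = 49` is calibrated to genome-scale SLGs holding hundreds to
thousands of scaftigs. Desk-scale synthetic communities (tens of scaftigs
per genome) use proportionally smaller values (`min_pts = 5` at ~40
scaftigs/genome in the shipped tests) and length thresholds scaled to the
50 kb genomes (25 kb); the decision rules are unchanged.

## Numerical and algorithmic choices

**Merge schedule.** The agglomeration repeatedly merges the pair of groups
with the highest inter-group edge density, subject to density ≥
`density_min`; ties prefer the larger combined length, then the
lexicographically smallest member id. This makes the SLG partition
deterministic and independent of input order. Constant (zero-variance)
depth rows have undefined correlation and receive no edges rather than
propagating NaNs.

**GC × depth scaling.** GC is already a fraction; depth is mapped through
log10(1 + depth) and min–max scaled per SLG so that the Euclidean `eps`
is meaningful on both axes — with one guard: the min–max span is floored
at 1 decade. Without the floor, an SLG whose depths differ only by noise
would have that noise stretched across [0, 1], and DBSCAN would read
spurious structure into a genuinely single-cluster group. With the floor,
within-cluster noise (a few hundredths of a decade) stays tight while
real multi-cluster separations (tens of an order of magnitude and more)
still spread far beyond `eps`. A zero span maps all points to one
coordinate. DBSCAN itself is the standard algorithm (scikit-learn), with
cluster indices re-assigned in order of first appearance in the input so
labels are reproducible; the test suite checks partition equality against
a brute-force density-reachability oracle.

**Depth for the 20× rule** is the length-weighted mean scaftig depth,
averaged over samples (pooled rather than per-sample — the rule is a
global coverage criterion, and pooling is the only convention that is
well defined for children that are absent from some samples).

**MUM detection** uses a generalized suffix array (numpy prefix doubling,
O(n log² n)) with a Kasai LCP pass. Members of a sequence set are joined
with unique sentinel codes so matches can never span member boundaries;
ambiguous bases also become unique sentinels and never match. A MUM is an
adjacent suffix pair from different sequences whose LCP is at least
`min_mum`, strictly exceeds both flanking LCPs (uniqueness in both
sequences), and whose preceding characters differ (left-maximality);
right-maximality is implied by the LCP being maximal. Only forward-strand
matches are considered; the generator produces forward-strand fragments,
and strand-aware matching would require reverse-complement indexing that
the downstream rules do not need.

**MUMi** is computed on the concatenated member sequences of each group.
MUM intervals are merged before measuring unmapped length, so overlapping
matches are not double-counted. The score is a similarity (1 = identical,
0 = unrelated); clustering joins pairs at or above the threshold by
single linkage, which is parameter-free beyond the threshold and gives
"could not be clustered" singletons a natural meaning. Floating-point
containment cases can exceed 1 by ~1e-16; no clamping is applied.

**Candidate-MAG reconstruction.** Clusters are merged by exact
suffix–prefix overlap (longest overlap first, ties by id), a conservative
stand-in for read-level reassembly that preserves the ≥ 500 bp
reliability rule exactly. The GC re-examination of candidate MAGs runs at
scaftig granularity *before* overlap merging, so sub-MAG membership and
the ≥ 90% SLG-coverage rule are measured in exactly attributable base
pairs; each sub-MAG is resolved against the original SLG that contributes
the most base pairs to it. Overlap merging then runs within each final
MAG. A practical consequence, faithful to the rules: two strains with very
different mean depths can MUMi-cluster and then be split back into two
revised MAGs by the depth axis — the re-examination is what protects
against chimeric combined MAGs.

**Permutation test.** The two-sided p-value is the smaller of the two
one-sided empirical tails with the +1 correction,
p = (1 + #{P_perm ≥ P_obs}) / (n_perm + 1) (≤ for depletion). With 999
draws the attainable minimum is 1/1000, and the discrete null rejection
rate at α = 0.01 is ≈ 0.018 when pooled over functions (each tail
contributes ≤ 9/1000). Draws are without replacement, so a minimal set
equal to the total set reproduces itself and every p-value is 1.

**Core curves** enumerate all C(S, n) sample combinations exactly
whenever the replicate budget covers them, and sample without replacement
otherwise; shared counts are then non-increasing and total counts
non-decreasing in n by construction.

**Whittaker β** is the pairwise excess form γ/ᾱ − 1 (0 for identical
samples); the ratio form γ/ᾱ is available via `variant="ratio"`.

## The synthetic-community generator

The generator emulates exactly the inputs the pipeline consumes: genomes
with controlled GC (per-base biased sampling, P(G or C) = target),
substitution-only strain variants at a nominal per-base rate (a
substitution always changes the base, so observed divergence matches the
rate), fragmentation into non-overlapping scaftigs of bounded length,
log-normal per-genome abundance profiles (a per-genome mean plus
per-sample variation, which guarantees co-abundance structure), and
per-scaftig depths equal to depth_scale × abundance times a unit-mean
log-normal factor with chosen CV. Breadth of coverage follows the
Poisson/Lander–Waterman expectation 1 − exp(−depth). Default study
conditions for the end-to-end check: 8 genomes × 50 kb with GC evenly
spaced in [0.3, 0.7], 24 samples, scaftigs 1,000–1,500 bp (~40 per
genome), depth scale 30×, noise CV 0.1. The 50 kb genome size keeps the
suffix-array and correlation work at desk scale while leaving ≥ 30
scaftigs per genome so the density-based stages operate in their intended
regime.

What the generator does **not** model: read-level sequencing error,
assembly artifacts (chimeras, collapsed repeats), indels and
rearrangements between strains, inter-genome homology (mobile elements,
conserved operons), GC-dependent coverage bias, and compositional
correlations between genomes. Passing tests therefore demonstrate that
the algorithms implement their rules correctly and recover well-separated
communities; they do not certify performance on real assemblies, where
repeat content and shared sequence make both the correlation graph and
MUM uniqueness noisier.

## Known limitations

- The co-abundance graph needs many samples (≥ ~10 informative ones) and
  between-sample abundance variation; a genome with flat abundance gives
  a zero-variance profile and is never binned.
- Edge density 0.99 effectively requires near-complete correlation
  cliques; scaftigs with a few missing edges drop out of their SLG
  (lowering completeness) rather than contaminate another.
- MUMi on repeat-rich genomes under-counts coverage because repeated
  substrings are never unique matches.
- The exact-overlap merger only joins sequences that overlap verbatim;
  it cannot close gaps or correct errors as a read-level assembler would.
- Taxonomy assignment consumes per-gene labels produced elsewhere; no
  classifier is bundled.
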