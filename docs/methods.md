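# Methods

## Data model: dominant scoring in a hexaploid

*Prunus domestica* is hexaploid, and capillary electrophoresis of SSR
amplicons yields peak patterns whose copy numbers cannot be phased into a
six-allele genotype. The package therefore scores genotypes dominantly: a
call is the set of distinct fragment lengths (1–6 integers, bp) an
accession shows at a locus; dosage is never inferred, and a size observed
once or three times collapses to presence. Every downstream statistic is
defined on carriers, not on allele copies.

Missing calls (a locus that failed to amplify for an accession) are
first-class: they are excluded from frequency denominators, deleted
pairwise in distances, treated as wildcards in fingerprinting comparisons
(a locus one accession lacks cannot prove a pair distinct — the
conservative choice for identification), and coded `-9` in the admixture
layout.

## Fragment-size binning

Raw fragment sizes drift by a few bp across instruments and runs. Sizes
are clustered by single linkage on the sorted values with a `min_step`
threshold (default 2 bp: it absorbs sub-bp jitter while keeping
dinucleotide-repeat alleles apart); each cluster is labelled by the
rounded median of its members, the mapping is monotone, and a cluster
spanning ≥ 3 × `min_step` triggers an over-merge warning. Binning is
idempotent on already-binned integers. When adjacent true alleles sit only
2 bp apart and jitter approaches the bin threshold, single linkage can
chain neighbouring alleles into one bin — an inherent limitation of
threshold binning, demonstrated in the stress tests with 2 bp grids and
large jitter; panel-wide recovery is exact when inter-allele spacing is
comfortably larger than the jitter spread (e.g. 4 bp spacing at 0.2 bp
jitter, the regime used for the recovery experiment).

## Diversity statistics

* **Carrier frequency** p_i = 100 × (accessions in the group carrying the
  allele) / (group accessions with a non-missing call at the locus),
  reported in percent. A reserved group name `pooled` unions all
  accessions.
* **Observed heterozygosity** Ho = fraction of accessions with ≥ 2
  distinct alleles at the locus. With dosage unknown this carrier-based
  definition is the only one available, and it is the one consistent with
  per-accession "homozygous at N loci" bookkeeping.
* **PIC (dominant form)** = mean over the locus's bands of 2f(1 − f) with
  f the carrier fraction; bounded by 0.5, maximized at f = 0.5, symmetric
  under f ↔ 1 − f. Codominant PIC is undefined without dosage. Reported at
  3 decimals; summary means of allele counts and Ho at 2 decimals, with
  half-up rounding to match how printed tables round.
* **Classification**: between two groups an allele is *common* iff carried
  in both, *unique* otherwise; *rare* iff every nonzero group frequency is
  ≤ the threshold (default 10%). Category counts, and their percentages of
  the pooled total at 1 decimal, are reported.

### The bundled printed tables

The fixture transcriptions are verbatim, including two typographic
anomalies in the source catalogue: one allele (BPPCT007, 134 bp) listed in
both the common and the group-unique column, and one bolded "rare" entry
(UDP98-407, 179 bp at 25%) that contradicts the stated ≤ 10% rule. The
fixture classifier counts printed entries (157 = 79 + 62 + 16) and
recomputes rarity from the frequency rule, which yields 9/49/16 rare
entries against the printed bolding's 8/50/16; the two disagreeing entries
are asserted explicitly in the tests. The general frequency-table
classifier, by contrast, operates on (group, locus, size) keys and would
collapse the duplicated allele to "common" (156 distinct alleles) — both
behaviours are intended and documented. Likewise one transcribed summary
table's per-locus allele numbers sum to 140 while its printed average row
implies 141; only internally consistent columns are used as regression
anchors.

## Minimal marker sets

Separation is formalized as pairwise profile inequality: a locus subset
discriminates a pair iff the two accessions' allele sets differ at a locus
both were scored at. The greedy procedure adds loci in strictly decreasing
PIC order (ties broken alphabetically) until no unresolved pair remains;
the unresolved count is non-increasing by construction. An exhaustive
enumerator (increasing subset size, then lexicographic; refused above 15
loci) provides the optimality oracle: the greedy set is never smaller than
the exhaustive minimum and both fully discriminate whenever any subset
can.

## Distances and UPGMA

Genotypes are recoded into a 0/1 band matrix (columns = (locus, size)
pairs; monomorphic columns flagged, not dropped). Distances between
accessions use Dice (default; the standard coefficient for dominant marker
data, weighting shared bands double), Jaccard or simple matching, with
pairwise deletion of columns under missing calls. A nucleotide
substitution distance is not computable from band data, so no such option
is offered.

UPGMA merges the closest pair at node height d/2 and updates distances by
the size-weighted mean (equivalently, the mean over all leaf pairs), which
keeps the output ultrametric; merge ties are broken by the
lexicographically smallest pair of minimal leaf labels so topologies are
bit-reproducible. Bootstrap support resamples band columns with
replacement (locus-block resampling available), rebuilds the tree, and
scores each reference clade by the percentage of replicates containing its
leaf set. Rendered Newick hides supports below 30% (the conventional
display cutoff) while retaining them on the tree object.

## Admixture model and ΔK

The sampler implements the standard admixture model on six-slot data:
each non-missing slot is an independent allele copy drawn from its
cluster's locus frequencies; since the writer stores each distinct allele
once, nothing is double-counted, but dosage is ignored — the same
approximation any dosage-blind polyploid analysis makes. Priors are
Dirichlet λ = 1 on cluster frequencies and fixed symmetric α = 1 on
admixture proportions (no α updating). lnP(X|K) is the posterior mean of
the data log-likelihood over post-burn-in sweeps — simpler than the
harmonic-mean-corrected estimator of the original software, and consistent
across K within the package, which is what second-difference model choice
requires. All updates are vectorized over observed slots; a fixed seed
yields bit-identical traces, and grid seeds derive as
`seed_base·1000 + K·100 + run`.

Evanno's ΔK(K) = |L(K+1) − 2L(K) + L(K−1)| / sd(L(K)) over replicate
runs; it is shift-invariant in lnP, needs ≥ 3 consecutive K with ≥ 2 runs,
and a zero sd is reported as an infinite sentinel with a warning. Q
matrices from replicate runs are aligned by greedy column matching on
correlation before averaging.

Default run-grid presets mirror a published-study scale (K = 1–20, 10
runs, burn-in 200 000, 500 000 iterations); the desk preset used
throughout the tests and the acceptance script scales this to K ≤ 6, 5
runs, burn-in 200–300 and 400–600 iterations on 45-accession panels — at
that size the vectorized sampler mixes well and the whole K-recovery
experiment completes in about a minute.

## Synthetic data generator

The generator emulates the study design the analyses assume: 9 loci with
8–21 alleles on a 2 bp grid (4 bp for the binning experiment), two to
three accession groups, per-group × locus allele frequencies drawn from a
symmetric Dirichlet whose concentration is the differentiation knob
(0.15–0.5 in the experiments: strongly structured groups; → ∞ approaches
identical spectra), six i.i.d. allele copies per accession collapsed to
the distinct set, and balanced hexaploid crosses in which each offspring
receives three copies sampled without replacement from a six-copy
expansion of each parent's allele set. Under copy sampling an allele at
frequency f is carried with probability 1 − (1 − f)^6, the transform used
when comparing empirical carrier rates to simulated frequencies.

What the generator does **not** emulate: real *P. domestica* meiosis
(preferential pairing, double reduction), linkage between loci, mutation,
null alleles, or genotyping dropout beyond simple missingness. Passing
recovery tests therefore show the pipeline's statistical machinery is
correct under its own model assumptions, not that any particular real
germplasm will separate as cleanly.

## Problem sizes and numerical choices

Tests and the acceptance script use: 50 random panels (≤ 12 loci, ≤ 20
accessions) for the marker-selection oracle; 16 accessions × ~100 bands
with 100–200 bootstrap replicates for split support; 45 accessions for the
admixture experiments (10 seeded repetitions of a K = 1..6 × 5-run grid);
six parents and 15 hybrids per pedigree repetition; 50 accessions for the
binning recovery. Ultrametricity is asserted to 1e-9; Dirichlet draws use
the gamma construction with padding positions masked to zero; Newick
labels containing metacharacters are single-quoted.

## Known limitations

* Rare alleles are over-represented under dominant scoring of polyploids;
  carrier-based p_i is not an allele-copy frequency and should not be fed
  into copy-frequency formulas.
* The admixture sampler has no linkage or correlated-frequencies model and
  does not estimate α; absolute lnP values are not comparable to other
  software, only across K within a run grid.
* The greedy marker set is not guaranteed minimal (the exhaustive oracle
  bounds it); with duplicate multilocus profiles no subset resolves the
  panel and the result is flagged unresolved.
* Threshold binning cannot separate alleles whose spacing is within the
  sizing jitter; inspect over-merge warnings on real data.
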