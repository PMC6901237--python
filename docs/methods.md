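# Methods

## Mutation model and normalization

The unit of analysis is a single somatic event against a haploid reference.
Substitutions are strand-symmetric: a G>T call and a C>A call describe the
same base-pair change, so every SSM is reported by the pyrimidine of the
mutated pair (six subtypes). Multi-base substitutions of equal ref/alt length
are decomposed into independent single-base events at their differing
positions; records that are neither a substitution nor a pure anchored indel
(complex alleles, symbolic alleles, non-ACGT bases) are dropped with a logged
count. Coordinates are 1-based VCF positions throughout; the conversion to
0-based indexing happens only inside the reference accessor. Chromosome
names are matched after stripping a `chr` prefix, and soft-masked lowercase
reference bases are treated as their uppercase equivalents.

Indels are left-aligned before anything else: the anchored representation is
rotated 5'-wards while the reference base at the anchor equals the last base
of the indel allele. This makes identical indels comparable across samples
and makes homopolymer-context counting one-directional. For a 1 bp deletion
the run length counts reference bases identical to the deleted base starting
*at* the deleted position and extending 3' (so the deleted base itself is
included); for a 1 bp insertion it counts reference bases identical to the
inserted base starting immediately 3' of the insertion point — reference
bases only, so an insertion before a non-matching base has run length 0 and
before a single matching base run length 1, both classed "none". "Same type"
means the identical base character, not the A/T–C/G pair: a run of
alternating A and T is not a mononucleotide repeat. Class boundaries are
none ≤ 1, short 2–4, midsize 5–7, long ≥ 8 bp. The insertion rule's treatment
of the inserted base was genuinely open; counting reference bases only is the
reading adopted here and is applied consistently in the generator and the
classifier.

## Recurrence

A mutation is recurrent in a scope (whole cohort, tumour type, cluster) when
its exact identity — contig, position, reference and alternate allele, and
class — is carried by ≥ 2 samples of that scope. Identity is allele-exact:
two different alternate alleles at one position are two distinct mutations.
Cohort-level summaries count each distinct mutation once regardless of how
many samples carry it; per-sample features instead ask what fraction of the
*sample's own* events is recurrent (the sample itself counts as one carrier,
so with the default threshold "recurrent" means at least one other carrier).
Degenerate denominators (a sample with no events of a class) yield 0 so the
feature matrix is complete.

The chance-recurrence null places each sample's mutation count as uniform
draws without replacement over a single genome of `genome_size` positions
(default 3.1e9, configurable) and reports the per-simulation percentage of
drawn positions hit by ≥ 2 samples, with 5,000 simulations by default. The
null deliberately ignores chromosome structure, mappability and sequence
composition: it answers only how much recurrence positional collision alone
would produce. When the null is compared against a generator whose
placements are constrained to compatible reference bases, the comparison
should be run per subtype at the compatible-site count (the acceptance
script does exactly this); at small genome sizes the simulation is validated
against exhaustive enumeration of the collision expectation. For large
genomes the simulator draws all samples jointly and resolves the rare
within-sample duplicates by redrawing, which leaves each sample exactly
uniform without replacement.

## The 42 features

Per genome: `n_ssm`, `n_sim` (absolute counts), `pct_sim_of_total`, the six
SSM-subtype percentages (of `n_ssm`), the four 1 bp SIM-subtype percentages
(of the 1 bp SIM count — multi-bp SIMs enter only the totals), and per 1 bp
SIM subtype the four homopolymer-class percentages (of that subtype's
count): 29 general features. Recurrence adds 13: overall recurrent-SSM and
-SIM percentages, the percentage of the sample's recurrent events that are
SIMs, and per-subtype recurrent percentages (six SSM + four SIM). Recurrence
for these features is always computed against the full-cohort index.
Homopolymer context is deliberately excluded from the recurrence block — at
realistic recurrent-SIM counts a 16-way stratification is too sparse to be
informative. Feature names and order are frozen in
`recurmut.features.FEATURE_NAMES` and written to every output header.

## Clustering

All 42 features are scaled to zero mean and unit variance with the
*population* standard deviation (denominator N); an implementation using
N−1 reproduces the same PCA up to a constant factor on the scores. PCA is
fitted in full; the retained dimensionality is the smallest number of leading
components whose cumulative explained-variance ratio reaches 0.80. Component
signs are fixed by making each component's largest-magnitude loading
positive. Ward clustering uses the D2 convention (merge cost = increase in
within-cluster sum of squares) on Euclidean distances of the retained
scores, with scipy's deterministic lowest-index tie-breaking. The cut at k
clusters is consolidated by Lloyd k-means started from the hierarchical
centroids for at most 10 iterations; a cluster emptied mid-iteration keeps
its previous centroid. Because total variance is fixed and each Lloyd pass
cannot increase the within-cluster sum of squares, the between-cluster
variance is non-decreasing across iterations (recorded in
`variance_history`). No automatic choice of k is implemented: k is an
explicit analysis decision, with k = 16 as the conventional default of the
cluster-tree reference resolution.

The v-test compares a cluster's feature mean to the cohort mean,
standardized by the sampling deviation of a random n_c-subset:
v = (x̄_c − x̄)/√((s²/n_c)·(N−n_c)/(N−1)) with population variance s²;
two-sided p-values come from the standard normal and are
Benjamini–Yekutieli-corrected over all cluster × feature tests as one
family. The variance convention (population vs sample) was an open choice;
population is used and documented. A constant feature gets v = 0, p = 1.

The cluster tree reruns cut + consolidation for every k in 2–20 on the same
retained-PC space (reusing one Ward linkage), links clusters at consecutive
resolutions by shared-sample counts (edges with proportion ≤ 0.1 relative to
the higher-resolution cluster are suppressed from reports), and marks for
each reference-resolution cluster the contiguous span of resolutions with a
Jaccard ≥ 0.85 counterpart. New samples are assigned by Euclidean distance
to the centroids in retained-PC space; distances within 1e-9 of the minimum
are reported as a tie set rather than silently broken. By default a new
sample's recurrence features should be computed against the reference cohort
only, which can underestimate them (the carrier threshold needs one partner
in the reference); rebuilding the index with the new sample included is the
caller's opt-in alternative.

## Motifs

Contexts are the ±10 reference bases around each stratum mutation, read on
the strand where the mutated base is the pyrimidine (the context of a
complemented call is reverse-complemented). This convention is required for
collapsed subtypes to have well-defined motifs and is applied uniformly.
Recurrent mutations contribute one context each regardless of carrier count;
mutations within 10 bp of a contig end are excluded with a logged count.
Per position, RE_i = Σ_b f(b_i) log₂(f(b_i)/P(b)) with 0·log 0 = 0, where the
prior P is estimated from the supplied reference with strand symmetrization
(P(A)=P(T), P(C)=P(G)) — portable to synthetic genomes, and reproducing the
human values when given the human reference. Signed per-base contributions
f·log₂(f/P) mark enrichment (+) and depletion (−) and are the bar heights of
the logo plot.

A motif is the set of positions with RE_i ≥ 0.25 plus the mutated position;
in ungapped mode only the maximal contiguous passing run through the mutated
site is reported, otherwise interior non-passing positions are bridged as N
and flagged. Each passing position is rendered as the IUPAC code of the
bases with positive contribution and frequency ≥ 0.25 (the representation
cutoff is a package parameter — no published rule exists for when a position
becomes degenerate; 0.25 makes a letter degenerate exactly when two bases
are jointly enriched above the uniform share). Genome background fractions
count non-overlapping k-windows (shift = k) across every contig and its
reverse complement, discarding windows with non-ACGT characters; an
overlapping mode (shift = 1) exists but is never the default because the
background percentages depend on the counting scheme. Enrichment of the
motif among recurrent vs non-recurrent contexts is a Pearson χ² on the 2×2
table without continuity correction; when an expected cell drops below 5 a
Fisher exact p is reported alongside with a warning.

## Statistics

Spearman correlations use average ranks with the t-approximation for
p-values; below n = 10 a permutation p-value replaces it. Benjamini–
Yekutieli is the only multiple-testing correction used — valid under the
arbitrary dependence that heavily correlated mutational features create —
with one family per analysis (all feature pairs jointly; all cluster ×
feature v-tests jointly). The two-group location test is the Wilcoxon
rank-sum with tie and continuity correction; fully tied data returns p = 1
with a warning.

## Synthetic data: what it emulates, and what it does not

Archetypes draw per-sample SSM and SIM loads log-normally
(count = median · e^{σz}), mirroring the orders-of-magnitude spread of real
cohorts. Subtype mixes are multinomial. Placement realizes three concrete
recurrence mechanisms: a fraction q of a target subtype's SSMs lands on
planted occurrences of a motif (sequence-context bias), a fraction on an
archetype-wide hotspot list (regional concentration), and 1 bp SIMs are
drawn from mononucleotide runs of the demanded context class — long runs are
scarce (planted at ~500 per base on the default 10 Mb reference), so an
archetype biased toward them concentrates its indels on few sites.
Everything else falls uniformly on base-compatible positions. Recurrence is
never planted as such; it emerges from this concentration, which is the
causal structure the analysis is meant to detect. Within-sample duplicate
draws are dropped, so heavily concentrated archetypes realize slightly fewer
events than drawn — the features describe the realized genome, as they would
for real data.

Default study conditions (used by the acceptance script and the end-to-end
tests): one 10 Mb contig at GC 0.40 with planted long-homopolymer tracts and
3,000 TTTCCT occurrences; four archetypes × 50 samples. UV-like: median
4,000 SSMs, 70% C>T, q = 0.35 on TTTCCT with the mutated C at offset 4.
MSI-like: median 2,500 SIMs against 1,200 SSMs, deletion-heavy, with 73% of
C/G deletions in midsize homopolymers. Tobacco-like: median 3,500 SSMs, 55%
C>A, no context preference. Neutral: median 600 SSMs, flat mix. Loads are
scaled to the 10 Mb toy genome (per-base rates comparable to the real
contrasts); the full pipeline at these sizes runs in ~2 minutes on one CPU.

Deliberately not emulated: diploidy and zygosity, chromatin/replication-
timing covariates of mutation rate, trinucleotide-signature structure beyond
the planted motif, sequencing error, and driver selection. Passing tests on
this generator therefore show that the pipeline recovers planted load,
subtype, context and concentration structure — not that real cohorts contain
such structure.

## Numerical choices and degenerate inputs

Constant feature columns scale to zero with unit scale and propagate as
all-zero columns; rank-deficient PCA keeps the available rank; a sample with
zero mutations yields an all-zero feature row with a prominent warning;
empty context strata and single-cluster v-tests are rejection errors rather
than NaNs. The k-means monotonicity assertion uses a 1e-9 slack for
floating-point noise. All stochastic operations take an explicit seed, and
the generator splits one cohort seed into per-archetype and per-sample
streams via `numpy` SeedSequence spawning, so adding samples to one
archetype does not perturb another's draws.

## Known limitations

Recurrence features couple samples: held-out assignment with reference-only
recurrence underestimates the recurrence block (documented caveat, opt-in
rebuild). The chance null is positional only; it is not a sequence-context-
aware background model. The motif caller is positional relative entropy, not
a de-novo finder — motifs not centred on the mutated base, or present in a
minority subpopulation of contexts, dilute below threshold. Genome
background fractions depend on the non-overlapping counting scheme and are
not comparable across k.
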