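# recurmut

**Recurrence-based mutational characterization and clustering of cancer
genomes.**

Identical somatic mutations observed at exactly the same genomic position in
two or more tumours — *recurrent* mutations — are improbable by chance alone
given the size of the genome, and driver selection explains only a handful of
them. Their abundance and type therefore carry a readable imprint of the
mutational processes that shaped each genome. `recurmut` turns that idea into
a reusable pipeline for cohorts of somatic mutation calls (SSMs: single-base
substitutions; SIMs: small insertions/deletions):

1. **Normalization** — VCF calls are split per alternate allele, adjacent
   substitutions are treated as separate single-base events, SSMs are
   collapsed onto the pyrimidine of the mutated base pair (six subtypes C>A,
   C>G, C>T, T>A, T>C, T>G), SIMs are left-aligned, and 1 bp SIMs are
   classified into A/T del, C/G del, A/T ins, C/G ins with their homopolymer
   context (none ≤1, short 2–4, midsize 5–7, long ≥8 bp).
2. **Recurrence** — cohort-wide indexes of carrier counts per distinct
   mutation, at pan-cancer / per-group scope, plus a Monte-Carlo null
   (default 5,000 simulations) for the recurrence expected if mutations fell
   uniformly on the genome.
3. **Features** — 42 features per genome: 29 general (loads, subtype and
   homopolymer-context distributions) and 13 recurrence-related
   (recurrent percentages overall and per subtype).
4. **Clustering** — features scaled to zero mean/unit variance (population
   convention), PCA keeping the smallest number of components explaining
   ≥ 80% of the variance, Ward (D2) hierarchical clustering of the retained
   scores, k-means consolidation seeded from the hierarchical centroids
   (≤ 10 iterations), per-cluster feature associations via the v-test

   v = (x̄_c − x̄) / √( (s²/n_c) · (N − n_c)/(N − 1) )

   with Benjamini–Yekutieli correction, a cluster-resolution tree with
   Jaccard stability spans, and nearest-centroid assignment of new samples.
5. **Motifs** — ±10 bp contexts of recurrent vs non-recurrent mutations on
   the pyrimidine strand, scored per position with the relative entropy

   RE_i = Σ_b f(b_i) · log₂( f(b_i) / P(b) )

   against genome base priors P; positions with RE_i ≥ 0.25 define the
   enriched motif (IUPAC letters for jointly enriched bases), whose genome
   background fraction comes from non-overlapping two-strand k-mer counting
   and whose recurrent-vs-non-recurrent enrichment is χ²-tested.
6. **Synthetic cohorts** — a generator of reference genomes and mutation
   cohorts drawn from latent process archetypes (UV-like, MSI-like,
   tobacco-like, neutral, or user-defined) where recurrence *emerges* from
   load, sequence-context bias and regional concentration, with ground-truth
   labels for end-to-end validation.

Intended users: computational cancer-genomics researchers who want to apply
the recurrence feature set to their own VCF cohorts, or to study when and why
recurrence-based clustering works, on fully controlled synthetic data.

## Worked example

```python
from recurmut.clustering import cluster_cohort, vtest_associations
from recurmut.features import assemble_feature_matrix
from recurmut.synthetic import (ReferenceSpec, default_archetypes,
                                generate_cohort, generate_reference, truth_report)

genome, elements = generate_reference(ReferenceSpec.default(2_000_000), seed=1)
cohort = generate_cohort([(a, 12) for a in default_archetypes()],
                         genome, elements, seed=4)
matrix = assemble_feature_matrix(cohort.normalized(genome))
pca, model = cluster_cohort(matrix, k=4)
print(pca.n_selected, truth_report(cohort.truth_labels, model.assignments).ari)
```

Running `python examples/03_cluster_genomes.py` (this code with reporting
around it) prints:

```
PCA: 5 components reach 81.8% variance
adjusted Rand index vs truth: 1.000
top positive association per cluster:
  cluster 0: pct_recurrent_ssm (v=6.8, p_BY=3.2e-09)
  cluster 1: pct_sim[A/T del][long] (v=6.8, p_BY=3.2e-09)
  cluster 2: pct_ssm[C>A] (v=6.6, p_BY=3.2e-09)
```

Five principal components carry ≥ 80% of the feature variance; the four
archetypes are recovered perfectly (ARI 1.0); and each cluster's strongest
positive association is the feature its archetype planted — the UV-like
cluster is flagged by its *recurrent*-SSM excess, the MSI-like one by
long-homopolymer A/T deletions, the tobacco-like one by its C>A share.
`examples/04_motif_discovery.py` continues the story: the recurrent C>T
stratum of the UV-like group calls the motif `TTTC[C]T` (mutated base
bracketed) at the RE ≥ 0.25 threshold, present in 63% of recurrent contexts
versus 0.1% of non-recurrent ones and 0.22% of genome 6-mers with C at that
offset.

The other examples cover cohort simulation with per-sample VCF output
(`01_simulate_cohort.py`) and the chance-recurrence null
(`02_recurrence_null.py`).

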