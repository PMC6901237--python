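"""Cluster cancer genomes on their 42 mutational features.

Computes the feature matrix (29 general + 13 recurrence features), scales it,
fits a PCA keeping enough components for >=80% of the variance, Ward-clusters
the scores and consolidates with k-means, then checks recovery against the
generating archetypes and lists each cluster's strongest feature
associations (v-test, Benjamini-Yekutieli corrected).  Finally a held-out
sample is assigned to its nearest centroid.
"""

from recurmut.clustering import assign_new_sample, cluster_cohort, vtest_associations
from recurmut.features import assemble_feature_matrix
from recurmut.synthetic import (
    ReferenceSpec,
    default_archetypes,
    generate_cohort,
    generate_reference,
    truth_report,
)

genome, element_map = generate_reference(ReferenceSpec.default(2_000_000), seed=1)
cohort = generate_cohort(
    [(a, 12) for a in default_archetypes()], genome, element_map, seed=4
)
norm = cohort.normalized(genome)
matrix = assemble_feature_matrix(norm, metadata=cohort.truth_labels)

# hold one sample out of the model fit (features still use cohort recurrence)
held_out = matrix.data.index[0]
training = matrix.data.drop(index=held_out)
from recurmut.features import FeatureMatrix

pca, model = cluster_cohort(FeatureMatrix(training), k=4)
print(f"PCA: {pca.n_selected} components reach "
      f"{100 * pca.explained_variance_ratio[:pca.n_selected].sum():.1f}% variance")
print(f"between-cluster variance: {model.between_cluster_variance:.2f} "
      f"(history {[round(v, 2) for v in model.variance_history]})")

report = truth_report(cohort.truth_labels.drop(held_out), model.assignments)
print(f"adjusted Rand index vs truth: {report.ari:.3f}")
print(report.confusion)

assoc = vtest_associations(FeatureMatrix(training), model.assignments)
print("\ntop positive association per cluster:")
sig = assoc[assoc.direction == "positive"]
for c, grp in sig.groupby("cluster"):
    best = grp.loc[grp.v_statistic.idxmax()]
    print(f"  cluster {c}: {best.feature} (v={best.v_statistic:.1f}, "
          f"p_BY={best.p_adjusted:.1e})")

a = assign_new_sample(matrix.data.loc[held_out], pca, model)
print(f"\nheld-out sample {held_out} ({cohort.truth_labels[held_out]}) -> "
      f"cluster {a.cluster}, distances {a.distances.round(2)}")
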