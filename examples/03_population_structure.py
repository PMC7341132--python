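"""Population structure: GRM, 1-IBS clustering, PCA and adjacent LD.

Reproduces the structure-analysis stage: VanRaden genomic relationships,
K-means (K=3) on principal coordinates of the 1-IBS distance matrix,
within/between-cluster relationship means, PCA variance fractions, and
per-chromosome adjacent-marker r².
"""

from sklearn.metrics import adjusted_rand_score

from haplogs import (SimConfig, adjacent_ld, cluster_relationships,
                     grm_vanraden, ibs_distance, kmeans_cluster, pca,
                     simulate_population)

cfg = SimConfig(seed=1)
pop = simulate_population(cfg)
g = pop.genotypes

grm = grm_vanraden(g)
assign = kmeans_cluster(ibs_distance(g), K=3, restarts=50, seed=0)
print("cluster sizes:", assign.labels.value_counts().sort_index().to_dict())
print("agreement with simulated pedigree clusters (ARI):",
      round(adjusted_rand_score(pop.true_cluster_labels, assign.labels), 3))

table = cluster_relationships(grm, assign)
print(table[["n_lines", "A_within", "A_between"]].round(3))
# A_within > A_between for every cluster: lines are more related inside
# their pedigree group than across groups.

coords, fracs = pca(g)
print(f"PC1 {100 * fracs[0]:.1f}% / PC2 {100 * fracs[1]:.1f}% of variance")

ld = adjacent_ld(g, pop.gmap)
print(f"genome-wide mean adjacent r2: {ld.genome_mean:.2f} "
      f"(per-chromosome range {ld.per_chromosome.min():.2f}-"
      f"{ld.per_chromosome.max():.2f})")
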