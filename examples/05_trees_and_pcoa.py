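"""Genetic distances, trees, and ordination between populations.

Computes Nei identity/distance between simulated populations, builds NJ
and UPGMA trees, cuts the UPGMA dendrogram at a similarity threshold,
and projects individuals with PCoA.
"""

from ilpkit import popgen, synthetic_data

genos, _ = synthetic_data.simulate_population_genotypes(
    n_loci=30, n_pops=4, n_per_pop=30, target_fst=0.08, seed=19)

S, D = popgen.pairwise_nei(genos)
print("Nei identity S:")
print(S.round(3).to_string())

tree = popgen.nj_tree(D)
print("\nNJ tree:", str(tree).strip())

nwk, clusters = popgen.upgma_tree(S, cut_threshold=float(S.to_numpy()[S.to_numpy() < 1].mean()),
                                  is_similarity=True)
print("UPGMA:", nwk)
print("clusters at mean similarity cut:", dict(clusters))

bands = synthetic_data.genotypes_to_bands(genos)
dm = popgen.band_distance_matrix(bands.df.iloc[:20])
res = popgen.pcoa(dm)
print("\nPCoA variance explained by first three axes: "
      + ", ".join(f"{v:.1f}%" for v in res.pct_variance[:3]))
# Populations separate along the leading coordinates in proportion to
# their Nei distances.
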