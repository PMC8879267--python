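"""Classical community statistics on the packaged toy survey.

Rank abundance shows which species dominate each site; rarefaction makes
richness comparable across unequal sampling effort; Bray-Curtis + UPGMA
cluster whole sites by compositional similarity.
"""

from vegnet import bray_curtis_matrix, rank_abundance, rarefaction_richness, upgma
from vegnet.datasets import toy_species, toy_survey
from vegnet.io import to_abundance_matrix

survey, meta = toy_survey(), toy_species()
matrices = [to_abundance_matrix(survey, s) for s in survey.sites]

for m in matrices:
    table = rank_abundance(m, meta).table
    top = table.iloc[0]
    print(
        f"{m.site_id}: N={m.total}, S={m.richness}, most abundant "
        f"{top.species_code} ({top.status}, p={top.relative_abundance:.2f})"
    )
    # expected richness if only 20 individuals had been sampled
    print(f"   E[S | n=20] = {rarefaction_richness(m.species_totals, 20):.2f}")

bc = bray_curtis_matrix(matrices)
print("\nBray-Curtis dissimilarity between sites:")
print(bc.round(3))
print("\nUPGMA dendrogram:", upgma(bc).to_newick())
# The two toy sites share all species but differ in which invader dominates,
# so their dissimilarity is driven by the LC/PJ abundance swap.
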