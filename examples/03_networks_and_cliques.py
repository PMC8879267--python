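"""Bipartite networks, community partitioning and hub species on the toy survey.

Each site becomes a two-mode graph (transects x species, presence/absence);
greedy modularity agglomeration partitions it, and each community's species
form a 'clique' whose highest-degree member is its hub.
"""

from vegnet import (
    build_bipartite,
    count_associations,
    extract_species_cliques,
    greedy_modularity_partition,
    simplify,
    to_abundance_matrix,
)
from vegnet.datasets import toy_species, toy_survey

survey, meta = toy_survey(), toy_species()

for site in survey.sites:
    g = simplify(build_bipartite(to_abundance_matrix(survey, site)))
    events, pairs = count_associations(g)
    part = greedy_modularity_partition(g)
    print(
        f"{site}: {g.number_of_edges()} edges, {events} association events "
        f"({pairs} unique pairs), Q = {part.q:.3f}"
    )
    for clique in extract_species_cliques(part, g, meta):
        hubs = ",".join(clique.hubs)
        print(
            f"   clique {clique.rank}: {clique.members} (hub {hubs}, "
            f"dominant invasive: {clique.dominant_invasive})"
        )
# Both sites split cleanly into an LC-anchored and a PJ-anchored clique:
# the two invaders never co-occur in a community.
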