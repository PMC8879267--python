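"""Superimpose focal-invader associations across the published six-site table.

All 25 cliques of the packaged community table are pooled; every co-member
of LC or PJ becomes a weighted partner (weight = number of cliques where the
association was seen), and partners are classified shared vs exclusive.
MCL on the combined weighted graph exposes the module structure.
"""

from vegnet import (
    cluster_combined,
    extract_focal_edges,
    merge_and_classify,
    site_exclusion_check,
)
from vegnet.datasets import ridge_cliques, ridge_species

cliques = ridge_cliques()
meta = ridge_species()

per_site, global_ok = site_exclusion_check(cliques, ("LC", "PJ"))
print(f"cliques: {len(cliques)} across {len(per_site)} sites")
print(f"LC/PJ exclusion per site: {per_site}")
print(f"global exclusion: {global_ok}")

graph = merge_and_classify(
    extract_focal_edges(cliques, "LC"), extract_focal_edges(cliques, "PJ")
)
print("\nmodule strengths (partners, total weight):")
for cls, strength in graph.module_strengths().items():
    print(f"   {cls}: {strength}")
print(f"shared partners: {graph.shared}")

_, modules = cluster_combined(graph, meta=meta)
print("\nMCL modules of the combined graph:")
for m in modules:
    print(f"   {m['members']} -> dominant class {m['dominant_class']}")
# Exclusive modules hold at least as many partners as the shared one: each
# invader keeps its own preferred set of native associates.
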