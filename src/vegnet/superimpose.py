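"""Cross-site superimposition of focal-invader associations.

After every site has been partitioned into species cliques, the pairwise
associations of two focal invaders (by default *Lantana camara*, LC, and
*Prosopis juliflora*, PJ) are pooled across all sites: each clique that
contains a focal contributes one observation of the association between the
focal and every co-member.  Edge weights therefore count the number of
cliques, pooled over sites, in which an association was observed.

Partners are classified **shared** (associated with both focals somewhere),
or **exclusive** to one focal; module strength is reported as (partner
count, total edge weight) per class.  A separate check verifies the
site-level exclusion pattern: the two focals never co-occurring in the same
clique at any site.  The combined weighted graph can be re-clustered with
MCL to expose the shared/exclusive module structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .io import SpeciesMetadata
from .mcl import MclParams, MclResult, mcl_cluster
from .partition import Clique

__all__ = [
    "FocalAssociationGraph",
    "extract_focal_edges",
    "merge_and_classify",
    "site_exclusion_check",
    "cluster_combined",
]


@dataclass
class FocalAssociationGraph:
    """Superimposed weighted partner associations of two focal species."""

    focal1: str
    focal2: str
    edges1: dict[str, int]  # partner -> number of cliques observed with focal1
    edges2: dict[str, int]
    shared: list[str] = field(default_factory=list)
    exclusive1: list[str] = field(default_factory=list)
    exclusive2: list[str] = field(default_factory=list)

    @property
    def partners(self) -> list[str]:
        return sorted(set(self.edges1) | set(self.edges2))

    def partner_class(self, partner: str) -> str:
        if partner in self.shared:
            return "shared"
        if partner in self.exclusive1:
            return f"exclusive_{self.focal1}"
        if partner in self.exclusive2:
            return f"exclusive_{self.focal2}"
        raise KeyError(partner)

    def module_strengths(self) -> dict[str, tuple[int, int]]:
        """(partner count, total edge weight) per module class."""

        def strength(partners: list[str]) -> tuple[int, int]:
            w = sum(self.edges1.get(p, 0) + self.edges2.get(p, 0) for p in partners)
            return len(partners), w

        return {
            "shared": strength(self.shared),
            f"exclusive_{self.focal1}": strength(self.exclusive1),
            f"exclusive_{self.focal2}": strength(self.exclusive2),
        }

    def to_graph(self) -> nx.Graph:
        """Weighted focal-partner graph for downstream clustering."""
        g = nx.Graph()
        g.add_node(self.focal1, role="focal")
        g.add_node(self.focal2, role="focal")
        for p in self.partners:
            g.add_node(p, role="partner", partner_class=self.partner_class(p))
        for p, w in self.edges1.items():
            g.add_edge(self.focal1, p, weight=w)
        for p, w in self.edges2.items():
            g.add_edge(self.focal2, p, weight=w)
        return g


def extract_focal_edges(cliques: list[Clique], focal: str) -> dict[str, int]:
    """Partner -> co-membership count for one focal over all cliques.

    Each clique containing the focal increments every co-member's weight by
    one; the focal never partners itself.
    """
    known = {s for c in cliques for s in c.members}
    if focal not in known:
        raise ValueError(f"focal species {focal!r} appears in no clique")
    weights: dict[str, int] = {}
    for clique in cliques:
        if focal not in clique.members:
            continue
        for partner in clique.members:
            if partner != focal:
                weights[partner] = weights.get(partner, 0) + 1
    return weights


def merge_and_classify(
    edges1: dict[str, int],
    edges2: dict[str, int],
    focal1: str = "LC",
    focal2: str = "PJ",
) -> FocalAssociationGraph:
    """Merge two focal partner maps; classify partners shared/exclusive."""
    set1, set2 = set(edges1), set(edges2)
    graph = FocalAssociationGraph(
        focal1=focal1,
        focal2=focal2,
        edges1=dict(edges1),
        edges2=dict(edges2),
        shared=sorted(set1 & set2),
        exclusive1=sorted(set1 - set2),
        exclusive2=sorted(set2 - set1),
    )
    return graph


def site_exclusion_check(
    cliques: list[Clique], focal_pair: tuple[str, str] = ("LC", "PJ")
) -> tuple[dict[str, bool], bool]:
    """Per-site and global check that two focals never share a clique.

    A site passes iff none of its cliques contains both focals; the global
    flag is the conjunction over sites.
    """
    f1, f2 = focal_pair
    per_site: dict[str, bool] = {}
    for clique in cliques:
        ok = not (f1 in clique.members and f2 in clique.members)
        per_site[clique.site_id] = per_site.get(clique.site_id, True) and ok
    return per_site, all(per_site.values())


def cluster_combined(
    graph: FocalAssociationGraph,
    params: MclParams | None = None,
    meta: SpeciesMetadata | None = None,
) -> tuple[MclResult, list[dict]]:
    """MCL modules of the combined weighted graph, annotated by class.

    Each module is reported with its dominant partner class (the most
    common among its non-focal members; ties broken alphabetically) and the
    focals it contains.
    """
    g = graph.to_graph()
    if g.number_of_nodes() == 0 or g.number_of_edges() == 0:
        raise ValueError("combined focal association graph is empty")
    result = mcl_cluster(g, params)
    report = []
    for cluster in result.clusters:
        focals = sorted(c for c in cluster if c in (graph.focal1, graph.focal2))
        partners = sorted(c for c in cluster if c not in focals)
        classes = [graph.partner_class(p) for p in partners]
        dominant = (
            min(sorted(set(classes)), key=lambda c: (-classes.count(c), c))
            if classes
            else None
        )
        module = {
            "members": sorted(cluster),
            "focals": focals,
            "dominant_class": dominant,
        }
        if meta is not None:
            module["statuses"] = {
                s: meta.status_of(s) for s in cluster if s in meta
            }
        report.append(module)
    return result, report
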