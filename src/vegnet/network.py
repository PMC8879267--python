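"""Bipartite species-transect networks and species projections.

Each site's abundance matrix becomes a two-mode undirected graph: transect
nodes and species nodes, with an edge wherever a species was recorded on a
transect (presence threshold: count >= 1 — abundance is kept for the
statistics, the network view is presence/absence).  Two species found on the
same transect are considered associated; the one-mode species projection
weights each species pair by the number of transects it shares.
"""

from __future__ import annotations

import itertools

import networkx as nx

from .io import AbundanceMatrix, transect_node_id

__all__ = [
    "build_bipartite",
    "simplify",
    "count_associations",
    "species_projection",
    "species_nodes",
    "transect_nodes",
]


def species_nodes(g: nx.Graph) -> list[str]:
    return sorted(n for n, d in g.nodes(data=True) if d.get("partite") == "species")


def transect_nodes(g: nx.Graph) -> list[str]:
    return sorted(n for n, d in g.nodes(data=True) if d.get("partite") == "transect")


def build_bipartite(matrix: AbundanceMatrix) -> nx.Graph:
    """Build the presence/absence bipartite graph of one site.

    Transect node ids are namespaced with the site code (``HK`` + ``1`` ->
    ``HK1``); all declared transects and species appear as nodes even if
    isolated, so node counts match the survey.
    """
    g = nx.Graph(site_id=matrix.site_id)
    t_ids = [transect_node_id(matrix.site_id, t) for t in matrix.transects]
    for t in t_ids:
        g.add_node(t, partite="transect")
    for s in matrix.species:
        g.add_node(s, partite="species")
    present = matrix.presence()
    for i, t in enumerate(t_ids):
        for j, s in enumerate(matrix.species):
            if present[i, j]:
                g.add_edge(t, s)
    return g


def simplify(g: nx.Graph | nx.DiGraph | nx.MultiGraph) -> nx.Graph:
    """Standardise a graph: undirected, deduplicated, self-loop free.

    Idempotent; node attributes are preserved.
    """
    out = nx.Graph(**g.graph)
    out.add_nodes_from(g.nodes(data=True))
    for u, v in g.edges():
        if u != v:
            out.add_edge(u, v)
    return out


def count_associations(g: nx.Graph) -> tuple[int, int]:
    """Count species association events and unique co-occurring pairs.

    Every pair of species present on the same transect is one association
    event; a transect holding d species therefore contributes C(d, 2)
    events.  The same species pair co-occurring on several transects counts
    once toward unique pairs.
    """
    events = 0
    pairs: set[tuple[str, str]] = set()
    for t in transect_nodes(g):
        neigh = sorted(g.neighbors(t))
        events += len(neigh) * (len(neigh) - 1) // 2
        pairs.update(itertools.combinations(neigh, 2))
    return events, len(pairs)


def species_projection(g: nx.Graph) -> nx.Graph:
    """One-mode species graph; edge weight = number of shared transects.

    Species that co-occur nowhere stay as isolated nodes so the species set
    is preserved.
    """
    proj = nx.Graph(site_id=g.graph.get("site_id"))
    for s in species_nodes(g):
        proj.add_node(s, partite="species")
    for t in transect_nodes(g):
        for a, b in itertools.combinations(sorted(g.neighbors(t)), 2):
            if proj.has_edge(a, b):
                proj[a][b]["weight"] += 1
            else:
                proj.add_edge(a, b, weight=1)
    return proj
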