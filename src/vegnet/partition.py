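"""Community detection on site networks and species-clique extraction.

The partitioning analogue of Cytoscape-style community layout tools is
greedy modularity agglomeration (Clauset-Newman-Moore): start from singleton
communities and repeatedly perform the merge with the largest modularity
gain while a strictly positive gain exists.  The implementation here is
fully deterministic — ties are broken by the lexicographically smallest
community label (a community is labelled by its smallest member node) — so
identical inputs always yield identical partitions.

From a partition of a bipartite site network, species-only "cliques" (the
field term for densely connected species communities, not graph-theoretic
complete subgraphs) are extracted: per community keep the species nodes,
drop communities with fewer than two species, rank by species count.  The
highest-degree species inside each clique's community subgraph are its
hubs, the keystone species of the assemblage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .io import SpeciesMetadata

__all__ = [
    "Partition",
    "Clique",
    "modularity",
    "greedy_modularity_partition",
    "extract_species_cliques",
    "identify_hubs",
]


@dataclass
class Partition:
    """Disjoint exhaustive communities of a graph, with their modularity Q."""

    communities: list[frozenset]
    q: float

    def __post_init__(self) -> None:
        seen: set = set()
        for c in self.communities:
            if seen & c:
                raise ValueError("communities must be disjoint")
            seen |= c

    def community_of(self, node) -> frozenset:
        for c in self.communities:
            if node in c:
                return c
        raise KeyError(node)


@dataclass
class Clique:
    """A species-only community at one site."""

    site_id: str
    rank: int
    members: list[str]  # species codes, sorted
    hubs: list[str] = field(default_factory=list)
    dominant_invasive: str | None = None

    @property
    def size(self) -> int:
        return len(self.members)


def modularity(g: nx.Graph, communities) -> float:
    """Newman-Girvan modularity Q of a node partition.

    Q = (1/2m) * sum_ij [A_ij - k_i*k_j/(2m)] * delta(c_i, c_j), evaluated
    per community as e_c/m - (d_c/2m)^2 with e_c the intra-community edge
    count and d_c the community degree sum.
    """
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("modularity undefined for a graph with no edges")
    nodes = set(g.nodes)
    covered: set = set()
    for c in communities:
        if covered & set(c):
            raise ValueError("communities must be disjoint")
        covered |= set(c)
    if covered != nodes:
        raise ValueError("partition must cover the graph exactly")
    q = 0.0
    for c in communities:
        cset = set(c)
        e_c = sum(1 for u, v in g.edges(cset) if u in cset and v in cset)
        d_c = sum(g.degree(n) for n in cset)
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


def _community_label(members: frozenset) -> str:
    return min(str(n) for n in members)


def greedy_modularity_partition(g: nx.Graph) -> Partition:
    """Clauset-Newman-Moore greedy modularity agglomeration.

    Starts from singleton communities; at each step the pair of connected
    communities with the largest modularity gain dQ is merged, while
    dQ > 0.  The gain of merging A and B is e_AB/m - 2*(d_A/2m)*(d_B/2m),
    so merges never cross connected components (e_AB = 0 gives dQ < 0).
    Ties on dQ are broken by the lexicographically smallest pair of
    community labels, making the procedure deterministic.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty graph")
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("cannot partition a graph with no edges")

    comms: dict[str, set] = {}
    node_comm: dict = {}
    for n in g.nodes:
        lab = str(n)
        comms[lab] = {n}
        node_comm[n] = lab
    degsum = {lab: g.degree(next(iter(c))) for lab, c in comms.items()}
    # inter-community edge counts, keyed by unordered label pair
    between: dict[tuple[str, str], int] = {}
    for u, v in g.edges:
        if u == v:
            continue
        a, b = sorted((node_comm[u], node_comm[v]))
        if a != b:
            between[(a, b)] = between.get((a, b), 0) + 1

    while between:
        best = None
        for (a, b), e_ab in between.items():
            dq = e_ab / m - 2 * (degsum[a] / (2 * m)) * (degsum[b] / (2 * m))
            key = (-dq, a, b)
            if best is None or key < best[0]:
                best = (key, a, b, dq)
        _, a, b, dq = best
        if dq <= 0:
            break
        # merge b into a (a < b lexicographically, so labels stay minimal)
        comms[a] |= comms.pop(b)
        for n in comms[a]:
            node_comm[n] = a
        degsum[a] += degsum.pop(b)
        merged: dict[tuple[str, str], int] = {}
        for (x, y), e in between.items():
            x = a if x == b else x
            y = a if y == b else y
            if x == y:
                continue
            pair = tuple(sorted((x, y)))
            merged[pair] = merged.get(pair, 0) + e
        between = merged

    communities = sorted(
        (frozenset(c) for c in comms.values()), key=_community_label
    )
    return Partition(communities, modularity(g, communities))


def extract_species_cliques(
    partition: Partition,
    g: nx.Graph,
    meta: SpeciesMetadata | None = None,
    *,
    min_species: int = 2,
) -> list[Clique]:
    """Species-only cliques from a bipartite-network partition.

    Communities are filtered to their species nodes; those with fewer than
    ``min_species`` species are noise for community tables and dropped.
    Cliques are ranked by species count descending (ties by first member
    code), hubs attached, and — when metadata is given — labelled with the
    code of an invasive hub if one exists.
    """
    site = g.graph.get("site_id", "")
    raw = []
    for comm in partition.communities:
        members = sorted(
            n for n in comm if g.nodes[n].get("partite") == "species"
        )
        if len(members) >= min_species:
            raw.append((members, comm))
    raw.sort(key=lambda ms: (-len(ms[0]), ms[0]))
    cliques = []
    for rank, (members, comm) in enumerate(raw, start=1):
        clique = Clique(site_id=site, rank=rank, members=members)
        clique.hubs = identify_hubs(clique, g, community=comm)
        if meta is not None:
            invasive_hubs = [h for h in clique.hubs if meta.status_of(h) == "invasive"]
            clique.dominant_invasive = invasive_hubs[0] if invasive_hubs else None
        cliques.append(clique)
    return cliques


def identify_hubs(clique: Clique, g: nx.Graph, *, community=None) -> list[str]:
    """Highest-degree species within the clique's community subgraph.

    Degree is taken in the site network restricted to the clique's
    community (species plus its transects).  All species tying at the
    maximum are reported, code-sorted.
    """
    if not clique.members:
        raise ValueError("clique has no members")
    if community is None:
        # fall back to the species' joint neighbourhood: members plus every
        # transect adjacent to a member
        community = set(clique.members)
        for s in clique.members:
            community |= set(g.neighbors(s))
    sub = g.subgraph(community)
    degrees = {s: sub.degree(s) for s in clique.members}
    top = max(degrees.values())
    return sorted(s for s, d in degrees.items() if d == top)
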