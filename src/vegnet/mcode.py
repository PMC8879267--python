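"""MCODE-style local-neighbourhood-density clustering.

Seed-and-expand detection of densely connected regions:

1. **Vertex weighting.**  For each node v, take the subgraph induced by its
   closed neighbourhood (v plus its neighbours), find the highest k-core of
   that subgraph, and set ``weight(v) = k * density(core)`` with density
   ``2E / (n (n - 1))``.  Isolated nodes weigh 0.
2. **Cluster expansion.**  Process unvisited nodes as seeds in order of
   decreasing weight (ties by node label).  From a seed, traverse outward,
   admitting a neighbour whose weight exceeds ``(1 - node_score_cutoff) *
   seed_weight``.  Traversal is confined to each expanding node's *local
   scoring core* — the edge (x, v) is only followed when v belongs to the
   highest k-core of x's closed neighbourhood.  This keeps expansion inside
   locally dense regions: two dense blocks joined by a single bridge edge
   are reported as two clusters, because the bridge edge lies outside both
   endpoints' scoring cores.
3. **Post-processing.**  Haircut removes singly-connected cluster members;
   fluff (off by default) adds neighbours whose neighbourhood density
   exceeds the fluff threshold.  Clusters of fewer than two nodes are
   dropped and the rest ranked by score = density * size.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

__all__ = ["McodeParams", "McodeCluster", "mcode_vertex_weights", "mcode_clusters"]


@dataclass
class McodeParams:
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    haircut: bool = True
    fluff: bool = False
    fluff_threshold: float = 0.2

    def __post_init__(self) -> None:
        if self.degree_cutoff < 0:
            raise ValueError("degree_cutoff must be >= 0")
        if not 0 <= self.node_score_cutoff <= 1:
            raise ValueError("node_score_cutoff must be in [0, 1]")
        if not 0 <= self.fluff_threshold <= 1:
            raise ValueError("fluff_threshold must be in [0, 1]")


@dataclass
class McodeCluster:
    rank: int
    members: list
    score: float
    seed: object


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2 * g.number_of_edges() / (n * (n - 1))


def _scoring_core(g: nx.Graph, v) -> tuple[int, set]:
    """Highest k-core of v's closed neighbourhood: (k, core node set)."""
    closed = set(g.neighbors(v)) | {v}
    sub = nx.Graph(g.subgraph(closed))
    sub.remove_edges_from(nx.selfloop_edges(sub))
    if sub.number_of_edges() == 0:
        return 0, {v}
    core_numbers = nx.core_number(sub)
    k = max(core_numbers.values())
    core = {n for n, c in core_numbers.items() if c >= k}
    return k, core


def mcode_vertex_weights(g: nx.Graph) -> dict:
    """weight(v) = k * density of the highest k-core of v's closed neighbourhood."""
    weights = {}
    for v in g.nodes:
        k, core = _scoring_core(g, v)
        if k == 0:
            weights[v] = 0.0
        else:
            weights[v] = k * _density(g.subgraph(core))
    return weights


def mcode_clusters(g: nx.Graph, params: McodeParams | None = None) -> list[McodeCluster]:
    """Ranked dense clusters via seeded outward traversal (see module docs).

    Nodes with graph degree below ``degree_cutoff`` neither seed nor join
    clusters.  Deterministic: all ties break on node label.
    """
    if params is None:
        params = McodeParams()
    weights = mcode_vertex_weights(g)
    eligible = {v for v in g.nodes if g.degree(v) >= params.degree_cutoff}
    cores = {v: _scoring_core(g, v)[1] for v in eligible}

    order = sorted(eligible, key=lambda v: (-weights[v], str(v)))
    visited: set = set()  # nodes claimed by a kept (multi-node) cluster
    seeded: set = set()
    raw_clusters: list[tuple[set, object]] = []
    for seed in order:
        if seed in visited or seed in seeded or weights[seed] <= 0:
            continue
        seeded.add(seed)
        threshold = (1 - params.node_score_cutoff) * weights[seed]
        cluster = {seed}
        frontier = [seed]
        while frontier:
            x = frontier.pop()
            for v in sorted(g.neighbors(x), key=str):
                if v in visited or v in cluster or v not in eligible:
                    continue
                if v not in cores[x]:
                    continue  # bridge edge out of x's locally dense region
                if weights[v] > threshold:
                    cluster.add(v)
                    frontier.append(v)
        if len(cluster) < 2:
            continue  # seed found no dense region; leave nodes available
        visited |= cluster
        raw_clusters.append((cluster, seed))

    clusters = []
    for members, seed in raw_clusters:
        if params.haircut:
            # iteratively shave nodes with < 2 connections inside the cluster
            changed = True
            while changed and len(members) > 2:
                sub = g.subgraph(members)
                shave = {v for v in members if sub.degree(v) < 2}
                changed = bool(shave)
                members = members - shave
        if params.fluff:
            extra = set()
            for v in members:
                for w in g.neighbors(v):
                    if w in members or w in extra:
                        continue
                    closed = set(g.neighbors(w)) | {w}
                    if _density(g.subgraph(closed)) > params.fluff_threshold:
                        extra.add(w)
            members = members | extra
        if len(members) < 2:
            continue
        sub = g.subgraph(members)
        clusters.append((sorted(members, key=str), _density(sub) * len(members), seed))

    clusters.sort(key=lambda c: (-c[1], c[0]))
    return [
        McodeCluster(rank=i, members=m, score=s, seed=seed)
        for i, (m, s, seed) in enumerate(clusters, start=1)
    ]
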