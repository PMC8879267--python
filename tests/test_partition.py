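import networkx as nx
import numpy as np
import pytest
from networkx.algorithms import community as nxcomm

from conftest import brute_force_best_modularity
from vegnet.io import AbundanceMatrix, SpeciesMetadata, SpeciesRecord
from vegnet.network import build_bipartite
from vegnet.partition import (
    Clique,
    extract_species_cliques,
    greedy_modularity_partition,
    identify_hubs,
    modularity,
)

META = SpeciesMetadata(
    [
        SpeciesRecord("LC", "Lantana camara", "invasive"),
        SpeciesRecord("PJ", "Prosopis juliflora", "invasive"),
        SpeciesRecord("AI", "Azadirachta indica", "introduced"),
        SpeciesRecord("ZN", "Ziziphus nummularia", "native"),
        SpeciesRecord("GRE", "Grewia tenax", "native"),
        SpeciesRecord("CS", "Capparis sepiaria", "native"),
        SpeciesRecord("AV", "Adhatoda vasica", "native"),
        SpeciesRecord("BR", "Balanites roxburghii", "native"),
    ]
)


class TestModularity:
    def test_single_community_is_zero(self, two_triangles_bridge):
        g = two_triangles_bridge
        assert modularity(g, [set(g.nodes)]) == pytest.approx(0.0)

    def test_two_triangles_bridge_value(self, two_triangles_bridge):
        g = two_triangles_bridge
        split = [{"a0", "a1", "a2"}, {"b0", "b1", "b2"}]
        assert modularity(g, split) == pytest.approx(5 / 14)

    def test_double_k4_bridge_value(self, double_k4_bridge):
        g = double_k4_bridge
        split = [{f"a{i}" for i in range(4)}, {f"b{i}" for i in range(4)}]
        assert modularity(g, split) == pytest.approx(11 / 26)

    def test_agrees_with_networkx(self, double_k4_bridge):
        g = double_k4_bridge
        split = [{f"a{i}" for i in range(4)}, {f"b{i}" for i in range(4)}]
        assert modularity(g, split) == pytest.approx(nxcomm.modularity(g, split))

    def test_edgeless_graph_rejected(self):
        g = nx.empty_graph(3)
        with pytest.raises(ValueError):
            modularity(g, [set(g.nodes)])

    def test_partial_cover_rejected(self, two_triangles_bridge):
        with pytest.raises(ValueError):
            modularity(two_triangles_bridge, [{"a0", "a1"}])


class TestGreedyPartition:
    def test_disconnected_triangles_stay_separate(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])
        g.add_edges_from([("x", "y"), ("y", "z"), ("x", "z")])
        part = greedy_modularity_partition(g)
        assert sorted(map(sorted, part.communities)) == [
            ["a", "b", "c"],
            ["x", "y", "z"],
        ]

    def test_double_k4_recovers_blocks_and_optimum(self, double_k4_bridge):
        g = double_k4_bridge
        part = greedy_modularity_partition(g)
        assert sorted(map(sorted, part.communities)) == [
            ["a0", "a1", "a2", "a3"],
            ["b0", "b1", "b2", "b3"],
        ]
        assert part.q == pytest.approx(brute_force_best_modularity(g))

    @pytest.mark.parametrize(
        "maker",
        [
            lambda: nx.path_graph(5),
            lambda: nx.cycle_graph(6),
            lambda: nx.karate_club_graph().subgraph(range(8)).copy(),
            lambda: nx.complete_bipartite_graph(3, 4),
            lambda: nx.barbell_graph(3, 1),
            lambda: nx.lollipop_graph(4, 2),
        ],
        ids=["path5", "cycle6", "karate8", "K34", "barbell", "lollipop"],
    )
    def test_attains_exhaustive_optimum_small_graphs(self, maker):
        g = nx.convert_node_labels_to_integers(maker())
        g = nx.relabel_nodes(g, {n: f"n{n}" for n in g.nodes})
        part = greedy_modularity_partition(g)
        assert part.q == pytest.approx(brute_force_best_modularity(g))

    def test_planted_bipartite_blocks_recovered(self):
        # two disconnected dense blocks of 3 transects + 4 species each
        counts = np.zeros((6, 8), dtype=int)
        counts[:3, :4] = 1
        counts[3:, 4:] = 1
        m = AbundanceMatrix(
            "S",
            [f"T{i}" for i in range(6)],
            ["LC", "ZN", "GRE", "CS", "PJ", "AV", "BR", "AI"],
            counts,
        )
        g = build_bipartite(m)
        part = greedy_modularity_partition(g)
        assert len(part.communities) == 2
        species_sets = sorted(
            sorted(n for n in c if not n.startswith("ST")) for c in part.communities
        )
        assert species_sets == [["AI", "AV", "BR", "PJ"], ["CS", "GRE", "LC", "ZN"]]
        assert part.q == pytest.approx(brute_force_best_modularity(g))

    def test_never_merges_across_components(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("c", "d"), ("e", "f")])
        part = greedy_modularity_partition(g)
        assert len(part.communities) == 3

    def test_reported_q_matches_recomputation(self, double_k4_bridge):
        part = greedy_modularity_partition(double_k4_bridge)
        assert part.q == pytest.approx(modularity(double_k4_bridge, part.communities))

    def test_empty_or_edgeless_rejected(self):
        with pytest.raises(ValueError):
            greedy_modularity_partition(nx.Graph())
        with pytest.raises(ValueError):
            greedy_modularity_partition(nx.empty_graph(2))

    def test_deterministic_across_node_orderings(self):
        g1 = nx.Graph()
        g1.add_edges_from([("b", "a"), ("c", "a"), ("b", "c"), ("d", "c")])
        g2 = nx.Graph()
        g2.add_edges_from(reversed([("b", "a"), ("c", "a"), ("b", "c"), ("d", "c")]))
        p1 = greedy_modularity_partition(g1)
        p2 = greedy_modularity_partition(g2)
        assert sorted(map(sorted, p1.communities)) == sorted(
            map(sorted, p2.communities)
        )


def bipartite_fixture():
    counts = np.array(
        [
            [1, 1, 1, 0],
            [1, 1, 0, 0],
            [0, 0, 0, 1],
        ]
    )
    m = AbundanceMatrix("S", ["T1", "T2", "T3"], ["LC", "ZN", "GRE", "PJ"], counts)
    return build_bipartite(m)


class TestCliqueExtraction:
    def test_transect_only_community_emits_nothing(self):
        g = bipartite_fixture()
        from vegnet.partition import Partition

        part = Partition(
            [frozenset({"ST1", "ST2", "ST3"}), frozenset({"LC", "ZN", "GRE", "PJ"})],
            0.0,
        )
        cliques = extract_species_cliques(part, g, META)
        assert len(cliques) == 1  # the transect-only community is skipped

    def test_species_filtered_and_sorted(self):
        g = bipartite_fixture()
        from vegnet.partition import Partition

        part = Partition(
            [frozenset({"ST1", "ST2", "LC", "ZN", "GRE"}), frozenset({"ST3", "PJ"})],
            0.0,
        )
        cliques = extract_species_cliques(part, g, META)
        assert len(cliques) == 1  # PJ singleton dropped (min 2 species)
        assert cliques[0].members == ["GRE", "LC", "ZN"]
        assert cliques[0].rank == 1

    def test_planted_blocks_give_matching_cliques(self):
        counts = np.zeros((6, 8), dtype=int)
        counts[:3, :4] = 1
        counts[3:, 4:] = 1
        m = AbundanceMatrix(
            "S",
            [f"T{i}" for i in range(6)],
            ["LC", "ZN", "GRE", "CS", "PJ", "AV", "BR", "AI"],
            counts,
        )
        g = build_bipartite(m)
        cliques = extract_species_cliques(greedy_modularity_partition(g), g, META)
        assert [c.members for c in cliques] == [
            ["AI", "AV", "BR", "PJ"],
            ["CS", "GRE", "LC", "ZN"],
        ]
        assert cliques[0].dominant_invasive == "PJ"
        assert cliques[1].dominant_invasive == "LC"


class TestHubs:
    def test_single_species_clique_is_its_own_hub(self):
        g = bipartite_fixture()
        clique = Clique("S", 1, ["PJ"])
        assert identify_hubs(clique, g) == ["PJ"]

    def test_star_centre_is_hub(self):
        g = bipartite_fixture()
        clique = Clique("S", 1, ["GRE", "LC", "ZN"])
        # LC and ZN each on 2 transects, GRE on 1 -> tie between LC and ZN
        assert identify_hubs(clique, g) == ["LC", "ZN"]

    def test_unique_hub_when_degrees_differ(self):
        counts = np.array([[1, 1, 0], [1, 0, 1], [1, 0, 0]])
        m = AbundanceMatrix("S", ["T1", "T2", "T3"], ["LC", "ZN", "GRE"], counts)
        g = build_bipartite(m)
        clique = Clique("S", 1, ["GRE", "LC", "ZN"])
        assert identify_hubs(clique, g) == ["LC"]
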