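import itertools

import networkx as nx
import pytest


def two_cliques_bridge(k: int) -> nx.Graph:
    """Two complete graphs K_k on labels a*/b*, joined by one bridge edge."""
    g = nx.Graph()
    a = [f"a{i}" for i in range(k)]
    b = [f"b{i}" for i in range(k)]
    g.add_edges_from(itertools.combinations(a, 2))
    g.add_edges_from(itertools.combinations(b, 2))
    g.add_edge(a[0], b[0])
    return g


@pytest.fixture
def two_triangles_bridge() -> nx.Graph:
    return two_cliques_bridge(3)


@pytest.fixture
def double_k4_bridge() -> nx.Graph:
    return two_cliques_bridge(4)


@pytest.fixture
def k4_pendant() -> nx.Graph:
    g = nx.complete_graph(["a", "b", "c", "d"])
    g.add_edge("a", "p")
    return g


@pytest.fixture
def three_leaf_star() -> nx.Graph:
    return nx.star_graph(["c", "l1", "l2", "l3"])


def set_partitions(items: list):
    """All set partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1 :]
        yield part + [[first]]


def brute_force_best_modularity(g: nx.Graph) -> float:
    """Exhaustive max modularity, per connected component (independent terms)."""
    from vegnet.partition import modularity

    best_total = 0.0
    for comp in nx.connected_components(g):
        best = None
        for part in set_partitions(sorted(comp)):
            m = g.number_of_edges()
            q = 0.0
            for c in map(set, part):
                e_c = sum(1 for u, v in g.edges(c) if u in c and v in c)
                d_c = sum(g.degree(n) for n in c)
                q += e_c / m - (d_c / (2 * m)) ** 2
            best = q if best is None else max(best, q)
        best_total += best
    # sanity: the helper agrees with the package's modularity on a partition
    assert modularity(g, list(nx.connected_components(g))) <= best_total + 1e-12
    return best_total


@pytest.fixture
def survey_csv(tmp_path):
    """The 3-row printed fixture: two transects, two species at site HK."""
    p = tmp_path / "survey.csv"
    p.write_text(
        "site,transect,species_code,count\n"
        "HK,HK1,LC,5\n"
        "HK,HK1,PJ,2\n"
        "HK,HK2,LC,1\n"
    )
    return p


@pytest.fixture
def species_csv(tmp_path):
    p = tmp_path / "species.csv"
    p.write_text(
        "code,scientific_name,status\n"
        "LC,Lantana camara,invasive\n"
        "PJ,Prosopis juliflora,invasive\n"
        "AI,Azadirachta indica,introduced\n"
        "ZN,Ziziphus nummularia,native\n"
    )
    return p
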