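# vegnet

Graph-theoretic analysis of transect-based vegetation surveys, built for
studying how invasive plants restructure woodland communities.

Classical vegetation analysis (ordination, clustering) summarises
community composition but is awkward for reading off *which species
associate with which*. `vegnet` takes the complementary network view: a
survey of line transects becomes, per site, a **bipartite co-occurrence
network** — transect nodes and species nodes, one edge per observed
occurrence — so that any two species recorded on the same transect are
"associated". Community detection on these networks yields species
assemblages ("cliques" in the field's usage — densely connected
communities, not complete subgraphs), each with its **hub** (highest-degree)
species. Pooling the cliques of two focal invaders across all sites then
separates the native flora into partners **shared** by both invaders and
partners **exclusive** to one — the community-level signature of
competitive exclusion between invaders.

## What it computes

Given a survey table (site, transect, species, count) and species metadata
(code, name, status ∈ {native, invasive, introduced}):

* **Community statistics** — relative/rank abundance `p_i = N_i / N`;
  analytic rarefaction
  `E[S_n] = Σ_i [1 − C(N−N_i, n) / C(N, n)]`;
  Bray–Curtis dissimilarity `1 − 2 Σ min(a_i, b_i) / (Σa + Σb)` between
  sites with UPGMA (average-linkage) clustering; a Pearson exclusion test
  on the relative abundances of two focal species (two-sided t, n−2 df).
* **Networks** — per-site bipartite presence/absence graphs (SIF and
  GraphML export), standardisation (undirected, deduplicated, loop-free),
  association counts (`Σ_t C(deg t, 2)` events; unique co-occurring
  pairs), and a weighted one-mode species projection.
* **Partitioning** — deterministic Clauset–Newman–Moore greedy modularity
  agglomeration (Newman–Girvan `Q`), and an MCODE-style
  local-neighbourhood-density clustering (vertex weight = k × density of
  the closed neighbourhood's highest k-core, seeded outward traversal,
  haircut/fluff post-processing). Cliques are the species members of each
  community, ranked by size, with hubs and dominant invasive labels.
* **Markov clustering (MCL)** — from-scratch flow simulation (expansion,
  inflation, pruning) for weighted species graphs, used to cluster the
  superimposed focal-association graph into shared/exclusive modules.
* **Synthetic surveys** — a seeded generator planting co-occurrence
  blocks, two mutually exclusive focal invaders, and anti-correlated
  site dominance, with ground truth returned for recovery scoring.

## Worked example

Partition the packaged toy survey (two sites, six transects, eight species)
and superimpose the focal invaders' associations from the packaged six-site
community table:

```bash
python examples/03_networks_and_cliques.py
```

```
HX: 18 edges, 18 association events (12 unique pairs), Q = 0.500
   clique 1: ['LC', 'NAA', 'NAB', 'NAC'] (hub LC, dominant invasive: LC)
   clique 2: ['NBA', 'NBB', 'NBC', 'PJ'] (hub PJ, dominant invasive: PJ)
HY: 18 edges, 18 association events (12 unique pairs), Q = 0.500
   clique 1: ['LC', 'NAA', 'NAB', 'NAC'] (hub LC, dominant invasive: LC)
   clique 2: ['NBA', 'NBB', 'NBC', 'PJ'] (hub PJ, dominant invasive: PJ)
```

Each site splits at modularity Q = 0.5 into an LC-anchored and a
PJ-anchored community: the two invaders never share a clique, each is the
hub of its own assemblage.

```bash
python examples/04_focal_superimposition.py
```

```
module strengths (partners, total weight):
   shared: (4, 11)
   exclusive_LC: (10, 13)
   exclusive_PJ: (7, 9)
shared partners: ['AI', 'BM', 'BR', 'DC']
```

Across the 25 published cliques of the six-site table, only four species
associate with both invaders; each invader keeps a larger exclusive partner
set, and MCL on the combined weighted graph splits it into one module per
invader.

Other examples: `01_simulated_survey.py` (generator design),
`02_community_statistics.py` (rank abundance, rarefaction, Bray–Curtis,
UPGMA), `05_full_pipeline_recovery.py` (end-to-end recovery scoring). A
thin CLI wraps the same library:

```bash
vegnet all --simulate --seed 1 --out out/          # full pipeline
vegnet partition --survey s.csv --species sp.csv --out out/
```

## Layout

```
src/vegnet/          io, ecostats, network, partition, mcode, mcl,
                     superimpose, synthetic, pipeline, cli, datasets
examples/            one narrative script per capability
tests/               pytest suite (unit, property, end-to-end)
docs/methods.md      models, parameters, numerical choices, limitations
```
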