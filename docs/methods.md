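# Methods

## The analysis model

The package treats a vegetation survey as evidence about species
*associations*: two species recorded on the same line transect are
associated, and repeated association across transects and sites is the
signal of interest. The unit of analysis is the per-site **bipartite
network** — transect nodes and species nodes, an edge wherever a species
was present on a transect (`count ≥ 1`; abundance is deliberately dropped
from the network view and kept for the statistics, so the network is
robust to count noise while the statistics retain it). Transect node ids
are namespaced by site code (`HK` + `1` → `HK1`) so species codes and
transect labels can share one graph namespace.

Communities ("cliques") are detected on the bipartite graph directly, not
on a one-mode projection: projections inflate density (every transect of
degree d becomes a d-clique) and lose which locations carry an
association. Both partitioners nevertheless accept a projection, and the
weighted projection (edge weight = shared-transect count) feeds the
superimposition step as an alternative weighting.

## Partitioning

**Greedy modularity (default).** Clauset–Newman–Moore agglomeration on the
simplified graph: start from singletons, repeatedly apply the merge with
the largest modularity gain `ΔQ = e_AB/m − 2 (d_A/2m)(d_B/2m)`, stop when
no strictly positive gain remains. Two implementation commitments matter
for reproducibility: ties on `ΔQ` are broken by the lexicographically
smallest pair of community labels (a community is labelled by its smallest
member), and reported `Q` is always recomputed from the partition by the
Newman–Girvan definition, never accumulated. Greedy agglomeration can miss
the modularity optimum on sparse chain-like graphs (a six-node path is the
smallest failure we know of); on dense planted-block graphs of the kind
surveys produce, it matches exhaustive search in all our fixtures.

**MCODE-style clustering (optional).** Vertex weight = `k × density` of
the highest k-core of the vertex's closed neighbourhood; clusters grow
from the highest-weighted unclaimed seed, admitting neighbours whose
weight exceeds `(1 − node_score_cutoff) × seed weight` (defaults: degree
cutoff 2, score cutoff 0.2, haircut on, fluff off — the algorithm's
published defaults). One design choice is ours: **traversal is confined to
each expanding node's local scoring core** — an edge is only followed if
it stays inside the highest k-core of the expanding node's closed
neighbourhood. Without this, a single bridge edge between two dense blocks
(both endpoints carrying full block weight) chains the blocks into one
cluster; with it, expansion follows locally dense structure only, and two
bridged K4s resolve into two clusters. Seeds whose expansion finds no
second member claim no nodes, so a high-weighted but sparse periphery
cannot starve later clusters. On bipartite graphs every neighbourhood is a
star (k = 1 cores), so MCODE there degenerates to connected dense regions;
it is most informative on weighted species projections.

**Cliques and hubs.** Per community, the species members form the clique
(communities with fewer than two species are reporting noise and are
dropped); cliques are ranked by species count, and the highest-degree
species within the community subgraph are the hubs — all ties reported,
code-sorted. An invasive hub makes that species the clique's "dominant
invasive" label.

## MCL

The Markov cluster algorithm is implemented dense (numpy): add self-loops
(weight 1.0 — the standard aperiodicity regularisation), column-normalise,
then iterate expansion (matrix power, default 2) and inflation (entrywise
power, default 2.0 — the classic granularity default — then renormalise),
zeroing entries below `1e-5` after each inflation. Convergence is max
entrywise change `< 1e-8`, a numerical stand-in for idempotency of the
flow matrix; non-convergence after 100 iterations warns and interprets
the current matrix. Attractors are nodes with positive return flow;
attractors supporting each other's rows are grouped, and every other node
joins the group receiving its largest flow (ties to the smallest
attractor label). Pruned and unpruned runs agree on every test graph up to
50 nodes; raising inflation never coarsened a clustering in our suite.

## Superimposition and exclusion

For each focal invader, every clique containing it contributes one
observation of the association with each co-member, pooled over sites —
so a partner's weight is the number of cliques in which the association
was seen (`--weight-by transects` substitutes shared-transect counts from
the projection instead). Partners present in both focals' maps are
**shared**; the set differences are **exclusive**. Module strength is
reported as (partner count, total weight) per class. The site-level
exclusion check is separate and purely combinatorial: a site passes if no
clique there contains both focals.

## Statistics

* **Rarefaction** is computed analytically as the hypergeometric
  expectation `E[S_n] = Σ_i [1 − C(N−N_i, n)/C(N, n)]`, with exact
  big-integer binomials (no log-gamma roundoff); a seeded Monte-Carlo
  resampling mode exists for cross-validation only. Deterministic output
  was preferred over resampling for testability.
* **Bray–Curtis / UPGMA**: sites are compared on species totals pooled
  over each site's transects (whole-site comparison). UPGMA is scipy's
  average-linkage behind the package's interface; merge heights are the
  merge dissimilarities themselves (not half-heights), and Newick branch
  lengths are parent-minus-child heights, so root-to-leaf path length
  equals the root merge height.
* **Pearson exclusion test**: product-moment r between the two focals'
  relative abundances, two-sided p from `t = r √((n−2)/(1−r²))`. The
  default sampling unit is the transect (within-site relative abundance,
  pooled across sites; transects with zero total are skipped) because it
  gives usable n; a per-site mode pairs the site totals, but with six
  sites it is underpowered (|r| ≥ 0.81 needed at α = 0.05) and is kept
  for descriptive use.

## The synthetic generator

The generator emulates the structure of a multi-fragment urban woodland
survey and provides the ground truth that field data cannot (such data is
rarely deposited). Design, with defaults:

| parameter | default | meaning |
|---|---|---|
| n_sites × transects_per_site | 6 × 15 | fragments and 250 m line transects |
| species | 45 native + 2 focal invasive + 3 introduced | survey-scale flora |
| blocks_per_site | 4 | planted co-occurrence blocks (2 focal-anchored) |
| p_in / p_out | 0.8 / 0.05 | within-block vs background occupancy |
| exclusion_strength γ | 1.0 | cross-focal block suppression |
| abundance_dispersion k | 4.0 | negative-binomial size (var = μ + μ²/k) |
| mean_abundance | 6.0 | individuals per occurrence (shifted NB, ≥ 1) |
| focal_dominance_range | (0.15, 0.85) | sites alternate between endpoints |
| dominance_boost | 12.0 | focal mean multiplier `1 + boost·w` |

Species are assigned to blocks globally (the same membership at every
site), transects per site round-robin over a shuffled order so every block
is represented. A species occurs on an own-block transect with probability
`p_in`, elsewhere with `p_out·(1 − γ·conflict)`, where *conflict* means a
focal-block species meeting the other focal's transects — at γ = 1 the two
focals' planted partner sets are therefore disjoint, the precondition for
exclusive-module recovery scoring. Each block's **anchor** (a focal, or
the lowest-coded native for native blocks) occupies *every* own-block
transect: that is what makes it the block's planted hub, and it mirrors
how dominant invaders blanket their sites in real surveys.

Counts are shifted negative binomial (`1 + NB`), overdispersed as clumped
vegetation counts are. Site dominance weights alternate deterministically
between the endpoints of `focal_dominance_range` — a mosaic of
LC-dominated and PJ-dominated fragments — and scale the two focals' mean
abundances in opposite directions. The tilt (boost 12, k = 4) is chosen so
the planted anti-correlation is strong relative to sampling noise, i.e.
the generator plants a *detectable* signal of the kind the method is meant
to find; with much heavier overdispersion the same construction still
tilts negative on average but ceases to be statistically identifiable at
this survey size.

Randomness: one master seed; the species-block assignment draws from a
global substream, and each site draws from a substream keyed by (seed,
site index), so adding sites never perturbs existing ones.

**What the generator does not emulate** — and hence what passing recovery
tests do not show about field data: spatial autocorrelation along and
between transects, environmental covariates driving occupancy, detection
error, temporal turnover, and partial (γ < 1) exclusion structure with
realistic overlap. Recovery results certify the machinery, not the
ecology.

## Degenerate inputs and numerical conventions

Empty graphs, edgeless graphs, all-zero abundance vectors, constant
correlation inputs and oversized rarefaction subsamples raise errors
rather than returning conventions. All orderings that could depend on hash
or insertion order are sorted (SIF rows by transect then species; cliques
by size then first member; all tie-breaks lexicographic), so every
artifact in an output bundle is byte-reproducible from config + seed; the
run manifest records both, plus a config hash, and re-running from the
manifest reproduces the bundle.

## Known limitations

* Greedy modularity has the usual resolution limit and can merge small
  true communities on sparse graphs; no resolution parameter is exposed.
* MCODE on unweighted bipartite graphs is weakly informative (star
  neighbourhoods); prefer the default partitioner there.
* The clique-count weighting of the superimposition treats all cliques
  equally regardless of clique size or site effort.
* Acceptance-scale results use 6 × 15 transects and 50 species, the
  design scale of the motivating survey type; behaviour at much larger
  scales is untested (the MCL implementation is dense, O(n³) per
  iteration).
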