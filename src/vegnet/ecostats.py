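"""Multivariate community statistics for transect surveys.

Covers the classical side of the analysis that complements the network view:

* **Rank abundance** — relative abundances :math:`p_i = N_i / N` per site,
  ranked descending, to show the extent to which invasive species dominate.
* **Rarefaction** — expected species richness in a random subsample of *n*
  individuals, computed analytically from the hypergeometric expectation
  :math:`E[S_n] = \\sum_i \\bigl[1 - \\binom{N-N_i}{n} / \\binom{N}{n}\\bigr]`,
  which makes sites of unequal sampling effort comparable.
* **Bray-Curtis dissimilarity** and **UPGMA** average-linkage clustering of
  sites, the standard abundance-based community comparison.
* A **Pearson exclusion test** between the relative abundances of two focal
  species — a significant negative correlation is the abundance-level
  signature of competitive exclusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import AbundanceMatrix, SpeciesMetadata

__all__ = [
    "RankAbundanceTable",
    "Dendrogram",
    "CorrelationResult",
    "rank_abundance",
    "rarefaction_richness",
    "rarefaction_curve",
    "rarefaction_richness_resampled",
    "bray_curtis",
    "bray_curtis_matrix",
    "upgma",
    "pearson_exclusion_test",
]


@dataclass
class RankAbundanceTable:
    """Ranked relative abundances for one site."""

    site_id: str
    table: pd.DataFrame  # columns: species_code, status, relative_abundance, rank

    def top(self, k: int) -> list[str]:
        return list(self.table["species_code"].iloc[:k])


@dataclass
class CorrelationResult:
    """Pearson product-moment correlation with a two-sided t test."""

    r: float
    p_value: float
    n: int
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


class Dendrogram:
    """UPGMA merge tree over sample labels.

    Wraps a scipy linkage matrix; merge heights are the merge dissimilarities
    (not half-heights), the common average-linkage convention.
    """

    def __init__(self, labels: list[str], linkage: np.ndarray):
        self.labels = list(labels)
        self.linkage = np.asarray(linkage, dtype=float)
        if self.linkage.shape != (len(self.labels) - 1, 4):
            raise ValueError("linkage shape inconsistent with label count")

    @property
    def heights(self) -> np.ndarray:
        """Merge heights, non-decreasing from first merge to root."""
        return self.linkage[:, 2]

    def cophenetic(self) -> np.ndarray:
        """Condensed cophenetic distance matrix (merge height per pair)."""
        return hierarchy.cophenet(self.linkage)

    def merges(self) -> list[tuple[frozenset[str], frozenset[str], float]]:
        """Merge events as (member set, member set, height) triples."""
        clusters: dict[int, frozenset[str]] = {
            i: frozenset([lab]) for i, lab in enumerate(self.labels)
        }
        out = []
        n = len(self.labels)
        for k, (a, b, h, _size) in enumerate(self.linkage):
            ca, cb = clusters[int(a)], clusters[int(b)]
            out.append((ca, cb, float(h)))
            clusters[n + k] = ca | cb
        return out

    def to_newick(self) -> str:
        """Render as a Newick string with branch lengths.

        A child's branch length is its parent's merge height minus its own
        (leaves have height 0), so root-to-leaf path lengths equal the root
        merge height.
        """
        tree = hierarchy.to_tree(self.linkage)

        def render(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left = render(node.left)
            right = render(node.right)
            bl_left = node.dist - node.left.dist
            bl_right = node.dist - node.right.dist
            return f"({left}:{bl_left:.6g},{right}:{bl_right:.6g})"

        return render(tree) + ";"


def rank_abundance(
    matrix: AbundanceMatrix, meta: SpeciesMetadata
) -> RankAbundanceTable:
    """Relative abundances p_i = N_i / N, ranked descending.

    Ties are broken by species code ascending so output is deterministic.
    """
    if matrix.total == 0:
        raise ValueError(f"site {matrix.site_id}: no individuals recorded")
    totals = matrix.species_totals
    df = pd.DataFrame(
        {
            "species_code": matrix.species,
            "status": [meta.status_of(s) for s in matrix.species],
            "relative_abundance": totals / matrix.total,
        }
    )
    df = df.sort_values(
        ["relative_abundance", "species_code"], ascending=[False, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return RankAbundanceTable(matrix.site_id, df)


def _validate_counts(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("counts must be a non-empty 1-D vector")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        arr = np.round(arr).astype(np.int64)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return arr[arr > 0]


def rarefaction_richness(counts, n: int) -> float:
    """Expected richness E[S_n] under random subsampling of n individuals.

    Each species i with N_i individuals out of N total is missed by the
    subsample with probability C(N-N_i, n)/C(N, n); summing the complement
    over species gives the hypergeometric expectation.  Evaluated with exact
    big-integer binomials, so there is no floating-point cancellation.
    """
    arr = _validate_counts(counts)
    total = int(arr.sum())
    if not 0 <= n <= total:
        raise ValueError(f"subsample size n={n} must be in [0, N={total}]")
    denom = math.comb(total, n)
    return float(sum(1 - math.comb(total - int(ni), n) / denom for ni in arr))


def rarefaction_curve(counts, sizes=None) -> pd.DataFrame:
    """E[S_n] for a grid of subsample sizes (default: 1..N)."""
    arr = _validate_counts(counts)
    total = int(arr.sum())
    if sizes is None:
        sizes = range(1, total + 1)
    return pd.DataFrame(
        {"n": list(sizes), "expected_richness": [rarefaction_richness(arr, n) for n in sizes]}
    )


def rarefaction_richness_resampled(
    counts, n: int, *, draws: int = 1000, rng=None
) -> float:
    """Monte-Carlo rarefaction: mean richness over random subsamples.

    Cross-validates the analytic expectation; not used by the pipeline.
    """
    arr = _validate_counts(counts)
    rng = np.random.default_rng(rng)
    pool = np.repeat(np.arange(arr.size), arr)
    richness = np.empty(draws)
    for d in range(draws):
        sub = rng.choice(pool, size=n, replace=False)
        richness[d] = np.unique(sub).size
    return float(richness.mean())


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min(a_i, b_i)) / (sum a + sum b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(1 - 2 * np.minimum(a, b).sum() / denom)


def bray_curtis_matrix(matrices: list[AbundanceMatrix]) -> pd.DataFrame:
    """Pairwise site dissimilarities from per-site pooled species totals.

    Counts are pooled over each site's transects (whole sites are compared),
    aligning species columns across sites with absent species at zero.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two sites")
    vectors = pd.DataFrame({m.site_id: m.species_vector() for m in matrices}).fillna(0.0)
    sites = list(vectors.columns)
    d = np.zeros((len(sites), len(sites)))
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            d[i, j] = d[j, i] = bray_curtis(
                vectors.iloc[:, i].to_numpy(), vectors.iloc[:, j].to_numpy()
            )
    return pd.DataFrame(d, index=sites, columns=sites)


def upgma(d: pd.DataFrame | np.ndarray, labels: list[str] | None = None) -> Dendrogram:
    """UPGMA (unweighted average-linkage) dendrogram of a dissimilarity matrix.

    The distance from a merged cluster to any other cluster is the arithmetic
    mean of all member-pair distances, i.e. size-weighted combination of the
    two children's distances.
    """
    if isinstance(d, pd.DataFrame):
        labels = list(d.index)
        mat = d.to_numpy(dtype=float)
    else:
        mat = np.asarray(d, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(mat.shape[0])]
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1] or mat.shape[0] < 2:
        raise ValueError("need a square dissimilarity matrix of size >= 2")
    if not np.allclose(mat, mat.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(mat), 0):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    linkage = hierarchy.linkage(squareform(mat, checks=False), method="average")
    return Dendrogram(labels, linkage)


def pearson_exclusion_test(x, y, *, alpha: float = 0.05) -> CorrelationResult:
    """Pearson correlation between two species' relative abundances.

    The units of observation are whatever the caller pairs up (transects by
    default in the pipeline; site totals in per-site mode).  p is two-sided
    from t = r*sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=n, alpha=alpha)
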