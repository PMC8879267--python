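import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import braycurtis as scipy_braycurtis

from vegnet.ecostats import (
    bray_curtis,
    pearson_exclusion_test,
    rank_abundance,
    rarefaction_richness,
    rarefaction_richness_resampled,
    upgma,
)
from vegnet.io import AbundanceMatrix, SpeciesMetadata, SpeciesRecord

META = SpeciesMetadata(
    [
        SpeciesRecord("AA", "Albizia amara", "native"),
        SpeciesRecord("BB", "Bombax malabarica", "native"),
        SpeciesRecord("CC", "Cassia fistula", "native"),
    ]
)


def matrix(counts, species):
    return AbundanceMatrix("X", [f"T{i}" for i in range(len(counts))], species, counts)


class TestRankAbundance:
    def test_single_species(self):
        t = rank_abundance(matrix([[9]], ["AA"]), META).table
        assert t.loc[0, "relative_abundance"] == 1.0
        assert t.loc[0, "rank"] == 1

    def test_hand_normalisation(self):
        t = rank_abundance(matrix([[6, 3, 1]], ["AA", "BB", "CC"]), META).table
        assert list(t["species_code"]) == ["AA", "BB", "CC"]
        assert np.allclose(t["relative_abundance"], [0.6, 0.3, 0.1])
        assert list(t["rank"]) == [1, 2, 3]

    def test_ties_break_by_code(self):
        t = rank_abundance(matrix([[2, 2]], ["BB", "AA"]), META).table
        assert list(t["species_code"]) == ["AA", "BB"]

    def test_empty_site_rejected(self):
        with pytest.raises(ValueError):
            rank_abundance(matrix([[0]], ["AA"]), META)


class TestRarefaction:
    def test_full_sample_returns_observed_richness(self):
        assert rarefaction_richness([5, 3, 2], 10) == pytest.approx(3.0)

    def test_single_species_always_one(self):
        for n in (1, 3, 7):
            assert rarefaction_richness([7], n) == pytest.approx(1.0)

    def test_two_pairs_enumeration(self):
        # all C(4,2)=6 subsamples of (2,2): 4 mixed pairs see 2 species,
        # 2 pure pairs see 1 -> E[S_2] = (4*2 + 2*1)/6 = 5/3
        assert rarefaction_richness([2, 2], 2) == pytest.approx(5 / 3)

    def test_exhaustive_enumeration_oracle(self):
        counts = [3, 2, 1]
        pool = [s for s, c in enumerate(counts) for _ in range(c)]
        for n in range(len(pool) + 1):
            expected = np.mean(
                [len(set(sub)) for sub in itertools.combinations(pool, n)]
            )
            assert rarefaction_richness(counts, n) == pytest.approx(expected)

    def test_oversized_subsample_rejected(self):
        with pytest.raises(ValueError):
            rarefaction_richness([2, 2], 5)

    def test_monotone_in_n(self):
        counts = [8, 4, 2, 1, 1]
        values = [rarefaction_richness(counts, n) for n in range(17)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(min_value=1, max_value=8), min_size=2, max_size=5),
        st.randoms(use_true_random=False),
    )
    def test_matches_monte_carlo_within_3se(self, counts, rnd):
        n = max(1, sum(counts) // 2)
        analytic = rarefaction_richness(counts, n)
        draws = 10_000
        rng = np.random.default_rng(rnd.randrange(2**31))
        pool = np.repeat(np.arange(len(counts)), counts)
        sample = np.array(
            [len(np.unique(rng.choice(pool, n, replace=False))) for _ in range(draws)]
        )
        se = sample.std(ddof=1) / math.sqrt(draws)
        assert abs(analytic - sample.mean()) <= max(3 * se, 1e-9)

    def test_resampled_mode_is_seed_stable(self):
        a = rarefaction_richness_resampled([4, 3, 2], 4, draws=200, rng=7)
        b = rarefaction_richness_resampled([4, 3, 2], 4, draws=200, rng=7)
        assert a == b


class TestBrayCurtis:
    def test_identical_vectors(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    def test_disjoint_supports(self):
        assert bray_curtis([1, 2, 0, 0], [0, 0, 3, 4]) == pytest.approx(1.0)

    def test_hand_evaluation(self):
        assert bray_curtis([1, 2, 3], [2, 1, 0]) == pytest.approx(5 / 9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(min_value=0, max_value=20), min_size=1, max_size=8),
        st.lists(st.integers(min_value=0, max_value=20), min_size=1, max_size=8),
    )
    def test_symmetric_bounded_and_matches_scipy(self, a, b):
        k = min(len(a), len(b))
        a, b = a[:k], b[:k]
        if sum(a) + sum(b) == 0:
            return
        d = bray_curtis(a, b)
        assert d == pytest.approx(bray_curtis(b, a))
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(scipy_braycurtis(a, b))
        if a == b:
            assert d == pytest.approx(0.0)


def brute_force_upgma(d: np.ndarray, labels):
    """Independent UPGMA: explicit cluster-size-weighted agglomeration.

    Clusters get fresh ids at each merge so updated distances can never be
    shadowed by stale leaf-pair entries.
    """
    clusters = {i: (frozenset([lab]), 1) for i, lab in enumerate(labels)}
    dist = {
        (i, j): d[i, j] for i in range(len(labels)) for j in range(i + 1, len(labels))
    }

    def get(a, b):
        return dist[(a, b)] if (a, b) in dist else dist[(b, a)]

    merges = []
    next_id = len(labels)
    while len(clusters) > 1:
        ids = sorted(clusters)
        h, i, j = min(
            (get(a, b), a, b) for ai, a in enumerate(ids) for b in ids[ai + 1 :]
        )
        (ca, na), (cb, nb) = clusters.pop(i), clusters.pop(j)
        merges.append((ca, cb, h))
        for cc in clusters:
            dist[(next_id, cc)] = (na * get(i, cc) + nb * get(j, cc)) / (na + nb)
        clusters[next_id] = (ca | cb, na + nb)
        next_id += 1
    return merges


class TestUpgma:
    def test_two_samples_single_merge(self):
        d = np.array([[0.0, 0.4], [0.4, 0.0]])
        dend = upgma(d, ["A", "B"])
        assert dend.heights.tolist() == [pytest.approx(0.4)]

    def test_hand_agglomeration(self):
        # d(A,B)=2, d(A,C)=8, d(B,C)=6: merge (A,B) at 2, then C at (8+6)/2=7
        d = np.array([[0, 2, 8], [2, 0, 6], [8, 6, 0]], dtype=float)
        dend = upgma(d, ["A", "B", "C"])
        merges = dend.merges()
        assert merges[0][:2] == (frozenset({"A"}), frozenset({"B"}))
        assert merges[0][2] == pytest.approx(2.0)
        assert merges[1][2] == pytest.approx(7.0)

    def test_ultrametric_input_reproduced_exactly(self):
        # perfect ultrametric: heights must reproduce the input distances
        d = np.array(
            [[0, 1, 4, 4], [1, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], dtype=float
        )
        dend = upgma(d, list("ABCD"))
        from scipy.spatial.distance import squareform

        assert np.allclose(squareform(dend.cophenetic()), d)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            upgma(np.array([[0, 1], [2, 0]], dtype=float), ["A", "B"])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=2, max_value=6), st.randoms(use_true_random=False))
    def test_matches_brute_force_agglomeration(self, n, rnd):
        rng = np.random.default_rng(rnd.randrange(2**31))
        m = np.round(rng.uniform(0.05, 1.0, size=(n, n)), 3)
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0.0)
        labels = [chr(65 + i) for i in range(n)]
        dend = upgma(d, labels)
        expected = brute_force_upgma(d, labels)
        got = dend.merges()
        assert [round(h, 9) for *_ , h in got] == [round(h, 9) for *_, h in expected]
        assert [frozenset(a | b) for a, b, _ in got] == [
            frozenset(a | b) for a, b, _ in expected
        ]

    def test_newick_has_all_leaves_and_additive_heights(self):
        d = np.array([[0, 2, 8], [2, 0, 6], [8, 6, 0]], dtype=float)
        nwk = upgma(d, ["A", "B", "C"]).to_newick()
        assert nwk.endswith(";")
        for leaf in "ABC":
            assert leaf in nwk


class TestPearsonExclusion:
    def test_perfect_anticorrelation(self):
        res = pearson_exclusion_test([1, 2, 3, 4], [-1, -2, -3, -4])
        assert res.r == pytest.approx(-1.0)

    def test_perfect_correlation(self):
        res = pearson_exclusion_test([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.r == pytest.approx(1.0)

    def test_textbook_fixture(self):
        res = pearson_exclusion_test([1, 2, 3, 4, 5], [2, 1, 4, 3, 6])
        assert res.r == pytest.approx(10 / math.sqrt(148))
        assert res.n == 5

    def test_p_value_limits(self):
        # |r| -> 1 gives p -> 0; r = 0 gives p = 1
        near = pearson_exclusion_test(
            [1, 2, 3, 4, 5, 6], [1.0001, 2, 3.0002, 4, 5.0001, 6]
        )
        assert near.p_value < 1e-6
        zero = pearson_exclusion_test([1, 2, 1, 2], [5, 5, 6, 6])
        assert zero.r == pytest.approx(0.0)
        assert zero.p_value == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson_exclusion_test([1, 1, 1], [1, 2, 3])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pearson_exclusion_test([1, 2], [3, 4])
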