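from itertools import combinations, permutations

import numpy as np
import pytest

from indets import (
    PairwiseMatrix,
    bray_curtis,
    geographic_distance,
    jaccard,
    raup_crick,
    read_pairwise,
    sorensen,
    write_pairwise,
)
from indets.community import PlotGeo

from conftest import make_table, random_table


class TestSimilarityIndices:
    def test_identical_and_disjoint_plots(self):
        t = make_table([[2, 3, 0, 0], [2, 3, 0, 0], [0, 0, 1, 4]])
        for fn in (bray_curtis, jaccard, sorensen):
            m = fn(t)
            assert m.values[0, 1] == pytest.approx(1.0)
            assert m.values[0, 2] == pytest.approx(0.0)

    def test_hand_computed_values(self):
        # BC: x=(2,0), y=(1,1) -> 1 - (1+1)/(3+1) = 0.5
        t = make_table([[2, 0], [1, 1]])
        assert bray_curtis(t).values[0, 1] == pytest.approx(0.5)
        # Jaccard: 2 shared of 5 distinct -> 0.4
        t = make_table([[1, 1, 1, 0, 1], [1, 1, 0, 1, 0]])
        assert jaccard(t).values[0, 1] == pytest.approx(2 / 5)
        # Sorensen: a=2, b=1, c=2 -> 4/7
        t = make_table([[1, 1, 1, 0, 0], [1, 1, 0, 1, 1]])
        assert sorensen(t).values[0, 1] == pytest.approx(4 / 7)

    def test_sorensen_jaccard_identity_and_binary_bray(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            t = random_table(rng)
            J = jaccard(t).values
            S = sorensen(t).values
            np.testing.assert_allclose(S, 2 * J / (1 + J), atol=1e-12)
            binary = make_table((t.abundance > 0).astype(int))
            np.testing.assert_allclose(
                bray_curtis(binary).values, sorensen(binary).values, atol=1e-12
            )

    def test_invariant_to_plot_reordering(self):
        rng = np.random.default_rng(7)
        t = random_table(rng, n_plots=7)
        perm = rng.permutation(7)
        t_perm = t.subset_plots([t.plot_ids[i] for i in perm],
                                drop_lost_species=False)
        for fn in (bray_curtis, jaccard, sorensen):
            a = fn(t).values
            b = fn(t_perm).values
            np.testing.assert_allclose(b, a[np.ix_(perm, perm)], atol=1e-12)

    def test_matrix_roundtrip(self, tmp_path):
        t = make_table([[2, 0], [1, 1]])
        m = bray_curtis(t)
        write_pairwise(m, tmp_path / "m.csv")
        back = read_pairwise(tmp_path / "m.csv")
        assert back.kind == "similarity"
        np.testing.assert_allclose(back.values, m.values)


# ---------------------------------------------------------------- Raup-Crick

def subset_prob(weights, subset):
    """Probability of drawing exactly `subset` (unordered) by sequential
    weighted sampling without replacement; exact, by recursion over the
    last element drawn."""
    W = weights.sum()
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def g(fs):
        if not fs:
            return 1.0
        total = 0.0
        w_fs = sum(weights[i] for i in fs)
        for t in fs:
            rest = tuple(x for x in fs if x != t)
            total += g(rest) * weights[t] / (W - w_fs + weights[t])
        return total

    return g(tuple(sorted(subset)))


def exact_raup_crick(presence, weights, i, j):
    """Exhaustive-enumeration beta_RC for the plot pair (i, j)."""
    S = presence.shape[1]
    a1 = int(presence[i].sum())
    a2 = int(presence[j].sum())
    ss_obs = int((presence[i] & presence[j]).sum())
    probs1 = {c: subset_prob(weights, c) for c in combinations(range(S), a1)}
    probs2 = {c: subset_prob(weights, c) for c in combinations(range(S), a2)}
    beta = 0.0
    for c1, p1 in probs1.items():
        s1 = set(c1)
        for c2, p2 in probs2.items():
            ss = len(s1 & set(c2))
            if ss > ss_obs:
                beta += p1 * p2
            elif ss == ss_obs:
                beta += 0.5 * p1 * p2
    return beta


class TestRaupCrick:
    def test_single_species_pool_forced_ties(self):
        t = make_table([[3], [5]], species_ids=["s0"])
        m = raup_crick(t, n_reps=25, seed=0)
        assert m.values[0, 1] == pytest.approx(0.5)  # SS* = SS = 1 always

    def test_deterministic_under_seed(self, small_table):
        a = raup_crick(small_table, n_reps=49, seed=13)
        b = raup_crick(small_table, n_reps=49, seed=13)
        assert np.array_equal(a.values, b.values)

    @pytest.mark.parametrize("frequency_weighted", [True, False])
    def test_matches_enumeration_oracle(self, frequency_weighted):
        rng = np.random.default_rng(21)
        n_reps = 999
        for case in range(6):
            n_species = int(rng.integers(4, 8))
            t = random_table(rng, n_plots=4, n_species=n_species, max_count=4)
            pres = t.presence()
            occ = pres.sum(axis=0).astype(float)
            weights = occ if frequency_weighted else np.ones(n_species)
            mc = raup_crick(t, n_reps=n_reps, seed=case,
                            frequency_weighted=frequency_weighted)
            for (i, j) in [(0, 1), (2, 3)]:
                exact = exact_raup_crick(pres, weights, i, j)
                # MC standard error of the mean of per-rep scores
                se = np.sqrt(max(exact * (1 - exact), 1e-4) / n_reps)
                assert abs(mc.values[i, j] - exact) < 3 * se + 1e-9, (
                    case, i, j, mc.values[i, j], exact
                )

    def test_similarity_view(self, small_table):
        m = raup_crick(small_table, n_reps=29, seed=1)
        s = m.to_similarity()
        np.testing.assert_allclose(s.values, 1 - m.values, atol=1e-12)
        assert np.allclose(np.diag(s.values), 1.0)


class TestGeographicDistance:
    def test_identical_coordinates_zero(self):
        g = PlotGeo(("a", "b"), "geographic",
                    np.array([-58.0, -58.0]), np.array([4.0, 4.0]))
        assert geographic_distance(g).values[0, 1] == 0.0

    def test_one_degree_meridian_arc(self):
        g = PlotGeo(("a", "b"), "geographic",
                    np.array([0.0, 0.0]), np.array([0.0, 1.0]))
        expected = np.pi / 180 * 6371.0
        assert geographic_distance(g).values[0, 1] == pytest.approx(expected,
                                                                    rel=1e-9)

    def test_planar_euclidean(self):
        g = PlotGeo(("a", "b"), "planar",
                    np.array([0.0, 3.0]), np.array([0.0, 4.0]))
        assert geographic_distance(g).values[0, 1] == pytest.approx(5.0)

    def test_metric_properties_random_triples(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            lon = rng.uniform(-180, 180, 3)
            lat = rng.uniform(-60, 60, 3)
            g = PlotGeo(("a", "b", "c"), "geographic", lon, lat)
            d = geographic_distance(g).values
            assert np.allclose(d, d.T)
            for i, j, k in permutations(range(3), 3):
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestPairwiseMatrixContract:
    def test_asymmetric_rejected(self):
        v = np.array([[0.0, 0.2], [0.4, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            PairwiseMatrix(("a", "b"), v, "dissimilarity")

    def test_bad_diagonal_rejected(self):
        v = np.array([[0.0, 0.5], [0.5, 0.0]])
        with pytest.raises(ValueError, match="diagonal"):
            PairwiseMatrix(("a", "b"), v, "similarity")

    def test_too_few_nonempty_plots_rejected(self):
        t = make_table([[0, 1], [0, 2], [5, 1]],
                       statuses=["identified", "unidentified"])
        from indets import subset_identified
        s = subset_identified(t)  # p0 and p1 become empty
        with pytest.raises(ValueError, match="non-empty"):
            bray_curtis(s)
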