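"""Cross-species summary statistics: Spearman, overlaps, decile windows."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from atlascmp.comparative import (
    decile_shared,
    hypergeom_overlap,
    overrepresentation,
    spearman_counts,
    tsg_divergence_overlap,
    tsg_overlap_tests,
)


class TestSpearmanCounts:
    def test_perfect_and_reversed_rankings(self):
        x = {"t1": 3, "t2": 9, "t3": 1, "t4": 6}
        rho, _ = spearman_counts(x, x)
        assert rho == pytest.approx(1.0)
        rev = {t: -v for t, v in x.items()}
        rho, _ = spearman_counts(x, rev)
        assert rho == pytest.approx(-1.0)

    def test_hand_computed_rho(self):
        rho, p = spearman_counts([1, 2, 3, 4, 5], [1, 2, 3, 5, 4])
        assert rho == pytest.approx(0.9)  # d² = 2 → 1 − 12/120
        # exact permutation two-sided tail: 10 of the 120 pairings
        assert p == pytest.approx(10 / 120)

    def test_exact_tail_matches_enumeration(self):
        x = [1, 2, 3, 4, 5, 6]
        y = [2, 1, 4, 3, 6, 5]
        rho_obs, p = spearman_counts(x, y)
        count = 0
        for perm in itertools.permutations(y):
            rho = np.corrcoef(np.argsort(np.argsort(x)), np.argsort(np.argsort(perm)))[0, 1]
            if abs(rho) >= abs(rho_obs) - 1e-12:
                count += 1
        assert p == pytest.approx(count / math.factorial(6))

    def test_invariant_under_monotone_transform(self):
        x = [3.0, 9.0, 1.0, 6.0, 4.0]
        y = [10, 40, 20, 50, 30]
        rho1, p1 = spearman_counts(x, y)
        rho2, p2 = spearman_counts([v**3 for v in x], [math.exp(v / 10) for v in y])
        assert rho1 == pytest.approx(rho2)
        assert p1 == pytest.approx(p2)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_counts([1, 1, 1], [1, 2, 3])


def _enumerated_upper_tail(n_univ, k_a, n_b, k):
    """Brute-force P(X ≥ k): count size-n_b subsets of the universe whose
    overlap with a fixed size-k_a set reaches k."""
    a_mask = (1 << k_a) - 1
    hits = total = 0
    for combo in itertools.combinations(range(n_univ), n_b):
        total += 1
        mask = sum(1 << i for i in combo)
        if bin(mask & a_mask).count("1") >= k:
            hits += 1
    return hits / total


class TestHypergeomOverlap:
    def test_complete_overlap_small_universe(self):
        universe = range(10)
        res = hypergeom_overlap(range(5), range(5), universe)
        assert res.overlap == 5
        assert res.p == pytest.approx(1 / 252)  # 1 / C(10,5)

    def test_zero_overlap_has_p_one(self):
        res = hypergeom_overlap({1, 2}, {3, 4}, range(10))
        assert res.overlap == 0
        assert res.p == 1.0

    def test_sets_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            hypergeom_overlap({99}, {1}, range(10))

    @pytest.mark.parametrize("n_univ", [5, 8])
    def test_matches_exhaustive_enumeration(self, n_univ):
        """Every feasible (|A|, |B|, overlap) combination agrees with a
        brute-force count over all draws from the universe."""
        universe = list(range(n_univ))
        for k_a in range(n_univ + 1):
            for n_b in range(n_univ + 1):
                k_min = max(0, k_a + n_b - n_univ)
                for k in range(k_min, min(k_a, n_b) + 1):
                    set_a = universe[:k_a]
                    set_b = universe[:k] + universe[k_a : k_a + n_b - k]
                    res = hypergeom_overlap(set_a, set_b, universe)
                    assert res.overlap == k
                    expected = _enumerated_upper_tail(n_univ, k_a, n_b, k)
                    assert res.p == pytest.approx(expected, abs=1e-12)

    def test_batch_bh_over_tissues(self, small_atlas):
        from atlascmp.de import call_tsg, tsg_sets

        em_a, em_b, omap, truth, _ = small_atlas
        pairs = omap.one_to_one_pairs()
        b_to_a = dict(zip(pairs["gene_b"], pairs["gene_a"]))
        universe = set(pairs["gene_a"])
        tsg_a = {t: s & universe for t, s in tsg_sets(call_tsg(em_a)).items()}
        tsg_b = {
            t: {b_to_a[g] for g in s if g in b_to_a}
            for t, s in tsg_sets(call_tsg(em_b)).items()
        }
        tab = tsg_overlap_tests(tsg_a, tsg_b, universe)
        # planted TSGs are shared across species: every tissue overlaps significantly
        assert (tab["fdr"] < 1e-4).all()
        assert (tab["overlap"] >= 1).all()


class TestDecileShared:
    def _profiles(self, values_a, values_b):
        genes = [f"g{i:03d}" for i in range(len(values_a))]
        pa = pd.DataFrame({"t": values_a}, index=genes)
        pb = pd.DataFrame({"t": values_b}, index=genes)
        return pa, pb

    def test_identical_profiles_share_every_window(self):
        vals = np.arange(50, dtype=float)
        pa, pb = self._profiles(vals, vals.copy())
        fractions = decile_shared(pa, pb, "t")
        assert (fractions == 1.0).all()

    def test_reversed_profiles_share_nothing(self):
        vals = np.arange(1.0, 41.0)
        pa, pb = self._profiles(vals, vals[::-1].copy())
        fractions = decile_shared(pa, pb, "t")
        assert (fractions == 0.0).all()

    def test_random_rankings_share_about_one_tenth(self):
        rng = np.random.default_rng(8)
        pa, pb = self._profiles(rng.uniform(size=1000), rng.uniform(size=1000))
        fractions = decile_shared(pa, pb, "t")
        assert ((fractions >= 0) & (fractions <= 1)).all()
        assert abs(fractions.mean() - 0.1) < 0.04

    def test_remainder_goes_to_top_windows(self):
        vals = np.arange(23, dtype=float)
        pa, pb = self._profiles(vals, vals.copy())
        fractions = decile_shared(pa, pb, "t", n_windows=10)
        assert len(fractions) == 10  # 3 windows of 3 genes, 7 of 2

    def test_fewer_genes_than_windows_rejected(self):
        pa, pb = self._profiles(np.arange(5.0), np.arange(5.0))
        with pytest.raises(ValueError, match="fewer genes"):
            decile_shared(pa, pb, "t", n_windows=10)


class TestTsgDivergenceOverlap:
    def test_contained_and_disjoint_sets(self):
        tab = tsg_divergence_overlap(
            {"t1": {"a", "b"}, "t2": {"c"}},
            {"t1": {"a", "b", "z"}, "t2": {"x"}},
            {"t1": {"q"}, "t2": {"y"}},
        )
        assert tab.loc["t1"].tolist() == [1.0, 0.0]
        assert tab.loc["t2"].tolist() == [0.0, 0.0]

    def test_empty_tsg_set_reported_missing(self):
        tab = tsg_divergence_overlap({"t1": set()}, {"t1": {"a"}}, {"t1": {"b"}})
        assert tab.loc["t1"].isna().all()


class TestOverrepresentation:
    def test_query_term_itself_is_most_significant(self):
        universe = [f"g{i}" for i in range(40)]
        query = set(universe[:8])
        annotation = {
            "self": set(query),
            "half": set(universe[:4]) | set(universe[20:24]),
            "other": set(universe[30:38]),
        }
        tab = overrepresentation(query, annotation, universe)
        assert tab.index[0] == "self"
        assert tab.loc["other", "p"] == 1.0  # disjoint term, k = 0

    def test_composition_matches_single_tests(self):
        universe = [f"g{i}" for i in range(30)]
        query = set(universe[:10])
        annotation = {"a": set(universe[5:15]), "b": set(universe[12:20])}
        tab = overrepresentation(query, annotation, universe)
        for term, members in annotation.items():
            single = hypergeom_overlap(members, query, universe)
            assert tab.loc[term, "p"] == pytest.approx(single.p)
            assert tab.loc[term, "overlap"] == single.overlap

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError, match="empty annotation"):
            overrepresentation({"g1"}, {}, {"g1"})
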