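"""Moderated-t engine: shrinkage, p-values, BH, and the calling drivers."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from atlascmp.core import Thresholds
from atlascmp.de import (
    EBPrior,
    bh_fdr,
    call_species_deg,
    call_tsg,
    eb_shrink,
    moderated_ttest,
    rank_divergence,
    species_deg,
    tsg_sets,
)


class TestEBShrink:
    def test_equal_variances_give_infinite_prior_df(self):
        prior, post = eb_shrink(np.full(10, 2.5), df=4)
        assert math.isinf(prior.d0)
        np.testing.assert_allclose(post, prior.s0_sq)

    def test_infinite_prior_pools_completely(self):
        prior = EBPrior(math.inf, 3.0)
        from atlascmp.de import posterior_variance

        post = posterior_variance(prior, np.array([0.1, 5.0, 2.0]), df=4)
        np.testing.assert_allclose(post, 3.0)

    def test_zero_prior_df_leaves_variances_alone(self):
        from atlascmp.de import posterior_variance

        s = np.array([0.5, 1.5, 9.0])
        np.testing.assert_allclose(posterior_variance(EBPrior(0.0, 1.0), s, 4), s)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            eb_shrink(np.zeros(5), df=4)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recovers_known_prior(self, seed):
        """Scaled-inverse-chi-square simulation with d0 = 4, s0² = 1, df = 4:
        the moment estimator recovers the generating prior."""
        rng = np.random.default_rng(seed)
        n, d0, s0_sq, df = 2000, 4.0, 1.0, 4
        sigma_sq = d0 * s0_sq / rng.chisquare(d0, n)
        s_sq = sigma_sq * rng.chisquare(df, n) / df
        prior, _ = eb_shrink(s_sq, df)
        assert 2.5 <= prior.d0 <= 6.5
        assert 0.8 <= prior.s0_sq <= 1.25


class TestModeratedTTest:
    def test_single_gene_matches_pooled_t_closed_form(self):
        res = moderated_ttest([[1.0, 2.0, 3.0]], [[3.0, 4.0, 5.0]])
        row = res.table.iloc[0]
        assert row["log2fc"] == pytest.approx(-2.0)
        assert row["t"] == pytest.approx(-2.449, abs=1e-3)
        assert row["df_total"] == 4
        assert row["p"] == pytest.approx(0.0705, abs=5e-4)

    def test_identical_groups_are_null(self):
        x = np.tile([[1.0, 2.0, 3.0]], (5, 1))
        res = moderated_ttest(x, x.copy())
        assert (res.table["log2fc"] == 0).all()
        np.testing.assert_allclose(res.table["p"], 1.0)

    def test_unshrunk_limit_equals_scipy_pooled_t(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=(60, 5)), rng.normal(size=(60, 7))
        res = moderated_ttest(a, b, prior=EBPrior(0.0, 1.0))
        ref = stats.ttest_ind(a, b, axis=1, equal_var=True)
        np.testing.assert_allclose(res.table["t"], ref.statistic, atol=1e-9)
        np.testing.assert_allclose(res.table["p"], ref.pvalue, atol=1e-9)

    def test_zero_variance_convention(self):
        a = np.array([[1.0, 1.0], [2.0, 2.0]])
        b = np.array([[1.0, 1.0], [5.0, 5.0]])
        res = moderated_ttest(a, b, prior=EBPrior(0.0, 1.0))
        assert res.table["p"].tolist() == [1.0, 0.0]

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError, match="two samples"):
            moderated_ttest([[1.0]], [[2.0, 3.0]])


class TestBHFdr:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    @pytest.mark.parametrize("p", [[1.0, 1.0, 1.0], [0.3]])
    def test_degenerate_vectors(self, p):
        np.testing.assert_allclose(bh_fdr(p), p)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_matches_reference_step_up(self, p):
        """Exact agreement with the statsmodels BH implementation, and the
        adjustment never ranks genes differently than the raw p-values."""
        from statsmodels.stats.multitest import multipletests

        ours = bh_fdr(p)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, ref, atol=1e-12)
        assert (ours >= np.asarray(p) - 1e-15).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(ours[order]) >= -1e-15).all()


class TestCallTsg:
    def test_constant_gene_never_called(self):
        from atlascmp.core import ExpressionMatrix

        rng = np.random.default_rng(3)
        values = pd.DataFrame(
            rng.lognormal(3, 1, size=(20, 6)),
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{j}" for j in range(6)],
        )
        values.loc["g0"] = 7.0  # flat across every sample
        meta = pd.DataFrame(
            {"species": "sp", "tissue": ["t1"] * 3 + ["t2"] * 3},
            index=values.columns,
        )
        results = call_tsg(ExpressionMatrix(values, meta))
        assert results and all(not r.table.loc["g0", "tsg"] for r in results.values())

    def test_undersized_tissue_skipped_with_warning(self, tiny_matrix):
        # brain has a single sample; liver's rest group is that single sample
        with pytest.warns(UserWarning, match="fewer than two samples"):
            results = call_tsg(tiny_matrix)
        assert results == {}

    def test_extreme_threshold_empties_calls(self, small_atlas):
        em_a = small_atlas[0]
        thr = Thresholds(tsg_log2fc=1e6)
        assert all(len(s) == 0 for s in tsg_sets(call_tsg(em_a, thr)).values())

    def test_calls_monotone_in_thresholds(self, small_atlas):
        em_a = small_atlas[0]
        loose = tsg_sets(call_tsg(em_a, Thresholds(tsg_log2fc=1.5, fdr=0.05)))
        strict = tsg_sets(call_tsg(em_a, Thresholds(tsg_log2fc=2.5, fdr=0.01)))
        for tissue, genes in strict.items():
            assert genes <= loose[tissue]

    def test_recovers_planted_tsgs(self, small_atlas):
        from atlascmp.evaluation import tsg_recovery

        em_a, em_b, _, truth, _ = small_atlas
        called_a = tsg_sets(call_tsg(em_a))
        called_b = tsg_sets(call_tsg(em_b))
        scores = tsg_recovery(truth, called_a, called_b)
        assert scores["recall"] >= 0.90
        assert scores["fdp"] <= 0.10


class TestSpeciesDeg:
    def test_identical_matrices_yield_no_degs(self, tiny_matrix):
        from atlascmp.core import ExpressionMatrix

        meta_b = tiny_matrix.metadata.copy()
        meta_b["species"] = "sp2"
        em_b = ExpressionMatrix(tiny_matrix.values.copy(), meta_b)
        res = call_species_deg(tiny_matrix, em_b, "liver")
        assert not res.table["deg"].any()
        np.testing.assert_allclose(res.table["log2fc"], 0.0, atol=1e-12)

    def test_swapping_species_negates_fold_changes(self, small_atlas):
        from atlascmp.orthology import align_one_to_one

        em_a, em_b, omap, _, _ = small_atlas
        al_a, al_b = align_one_to_one(em_a, em_b, omap)
        fwd = call_species_deg(al_a, al_b, "tissue_01")
        rev = call_species_deg(al_b, al_a, "tissue_01")
        np.testing.assert_allclose(
            fwd.table["log2fc"].to_numpy(), -rev.table["log2fc"].to_numpy(), atol=1e-12
        )

    def test_planted_tissue_has_most_degs(self, small_atlas):
        from atlascmp.orthology import align_one_to_one

        em_a, em_b, omap, truth, cfg = small_atlas
        al_a, al_b = align_one_to_one(em_a, em_b, omap)
        results = species_deg(al_a, al_b)
        counts = {t: int(r.table["deg"].sum()) for t, r in results.items()}
        planted_tissue = next(iter(truth.deg_a))
        assert counts[planted_tissue] == max(counts.values())
        assert counts[planted_tissue] > 0

    def test_absent_tissue_rejected(self, small_atlas):
        from atlascmp.orthology import align_one_to_one

        em_a, em_b, omap, _, _ = small_atlas
        al_a, al_b = align_one_to_one(em_a, em_b, omap)
        with pytest.raises(ValueError, match="absent"):
            call_species_deg(al_a, al_b, "no_such_tissue")


class TestRankDivergence:
    def _result(self, p, lfc, genes):
        table = pd.DataFrame(
            {"log2fc": lfc, "t": 0.0, "df_total": 4.0, "p": p, "fdr": p},
            index=pd.Index(genes, name="gene_id"),
        )
        from atlascmp.de import DEResult

        return {"t1": DEResult(table, EBPrior(0.0, 1.0))}

    def test_sizes_and_disjointness(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i:03d}" for i in range(100)]
        res = self._result(rng.uniform(size=100), rng.normal(size=100), genes)
        div, con = rank_divergence(res)["t1"]
        assert len(div) == len(con) == 10
        assert not div & con

    def test_all_ties_fall_back_to_fold_change(self):
        genes = ["g1", "g2", "g3", "g4"]
        res = self._result([0.5] * 4, [0.1, 3.0, 0.2, 2.0], genes)
        div, con = rank_divergence(res, Thresholds(divergence_fraction=0.25))["t1"]
        assert div == {"g2"}  # largest |log2fc| wins the tie
        assert con == {"g1"}  # smallest |log2fc|, gene id breaks the rest

    def test_planted_degs_enriched_in_divergent_set(self, small_atlas):
        from atlascmp.orthology import align_one_to_one

        em_a, em_b, omap, truth, _ = small_atlas
        al_a, al_b = align_one_to_one(em_a, em_b, omap)
        results = species_deg(al_a, al_b)
        tissue, planted = next(iter(truth.deg_a.items()))
        divergent, _ = rank_divergence(results)[tissue]
        k = len(divergent & planted)
        universe = len(results[tissue].table)
        p = stats.hypergeom.sf(k - 1, universe, len(planted), len(divergent))
        assert p < 0.01
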