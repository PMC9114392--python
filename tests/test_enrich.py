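import numpy as np
import pandas as pd
import pytest
from scipy import stats

import apaenrich as ap
from apaenrich.classify import GENE_NOT_UP, SU_UP
from apaenrich.enrich import (
    assign_strata,
    contingency_chisq,
    enrichment_by_category,
    make_strata,
    stratified_enrichment,
)


def brute_force_chisq(a, b, c, d):
    """Pearson chi-square via the expected-counts formulation."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    n = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    return ((obs - exp) ** 2 / exp).sum()


class TestContingencyChisq:
    def test_homogeneous_table_is_zero(self):
        res = contingency_chisq(10, 10, 10, 10)
        assert res.chi2 == 0.0
        assert res.p_value == 1.0
        assert res.odds_ratio == 1.0

    def test_closed_form_value_12_5(self):
        assert contingency_chisq(30, 70, 10, 90).chi2 == pytest.approx(12.5)

    def test_closed_form_value_19_2_with_or_9(self):
        # 50% vs 10% enhancer-associated, group sizes 20 vs 100
        res = contingency_chisq(10, 10, 10, 90)
        assert res.chi2 == pytest.approx(19.2)
        assert res.odds_ratio == pytest.approx(9.0)
        assert res.frac_group == pytest.approx(0.5)
        assert res.frac_reference == pytest.approx(0.1)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            contingency_chisq(0, 0, 5, 5)

    def test_matches_brute_force_on_margin_sweep(self):
        # exhaustive oracle over small tables (full sweep in acceptance)
        for a in range(0, 8):
            for b in range(0, 8):
                for c in range(0, 8):
                    for d in range(0, 8):
                        if min(a + b, c + d, a + c, b + d) == 0:
                            continue
                        res = contingency_chisq(a, b, c, d)
                        assert res.chi2 == pytest.approx(
                            brute_force_chisq(a, b, c, d), abs=1e-9
                        )

    def test_continuity_correction_reduces_statistic(self):
        plain = contingency_chisq(10, 10, 10, 90).chi2
        corrected = contingency_chisq(10, 10, 10, 90, continuity=True).chi2
        assert corrected < plain
        expected = stats.chi2_contingency(
            [[10, 10], [10, 90]], correction=True
        ).statistic
        assert corrected == pytest.approx(expected)


def toy_categories(n_group=20, n_ref=100, lfc_group=0.2, lfc_ref=0.0):
    genes = [f"g{i}" for i in range(n_group + n_ref)]
    cat = [SU_UP] * n_group + [GENE_NOT_UP] * n_ref
    lfc = [lfc_group] * n_group + [lfc_ref] * n_ref
    return pd.DataFrame(
        {"category": cat, "gene_log2fc": lfc}, index=pd.Index(genes, name="gene_id")
    )


class TestEnrichmentByCategory:
    def test_toy_fractions_and_chi2(self):
        cats = toy_categories()
        flags = pd.Series(
            [True] * 10 + [False] * 10 + [True] * 10 + [False] * 90,
            index=cats.index,
        )
        res = enrichment_by_category(cats, flags)[SU_UP]
        assert res.frac_group == pytest.approx(0.5)
        assert res.frac_reference == pytest.approx(0.1)
        assert res.chi2 == pytest.approx(19.2)

    def test_reference_must_differ(self):
        cats = toy_categories()
        flags = pd.Series(True, index=cats.index)
        with pytest.raises(ValueError):
            enrichment_by_category(cats, flags, reference_category="GENE_UP")

    def test_shuffled_flags_reject_at_alpha(self, classified):
        rng = np.random.default_rng(0)
        flags = pd.Series(
            rng.random(len(classified)) < 0.2, index=classified.index
        )
        rejections = 0
        n_shuffles = 200
        for _ in range(n_shuffles):
            shuffled = pd.Series(
                rng.permutation(flags.to_numpy()), index=flags.index
            )
            res = enrichment_by_category(classified, shuffled)[SU_UP]
            rejections += res.p_value < 0.05
        assert rejections / n_shuffles == pytest.approx(0.05, abs=0.04)


class TestStrata:
    def test_printed_bounds_give_width_5_13(self):
        edges = make_strata([-4.0, 0.0, 0.5], n_strata=13, upper=1.0)
        assert len(edges) == 14
        assert edges[0] == -4.0 and edges[-1] == 1.0
        assert np.allclose(np.diff(edges), 5.0 / 13.0)

    def test_upper_edge_is_closed(self):
        edges = make_strata([-4.0], n_strata=13, upper=1.0)
        idx = assign_strata(pd.Series({"g": 1.0}), edges)
        assert idx["g"] == 12

    def test_out_of_bounds_excluded(self):
        edges = make_strata([-4.0], n_strata=13, upper=1.0)
        idx = assign_strata(pd.Series({"hi": 1.2, "lo": -4.5}), edges)
        assert (idx == -1).all()

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            make_strata([2.0], n_strata=13, upper=1.0)


class TestStratifiedEnrichment:
    def test_min_rule_per_stratum(self):
        cats = toy_categories(n_group=3, n_ref=5, lfc_group=0.5, lfc_ref=0.5)
        flags = pd.Series([True, False] * 4, index=cats.index)
        res = stratified_enrichment(cats, flags, n_repeats=2, seed=0, n_strata=1)
        for rep in res.repeats:
            assert len(rep.sampled_group) == 3
            assert len(rep.sampled_reference) == 3

    def test_matched_counts_equal_every_repeat(self, classified):
        flags = pd.Series(
            np.random.default_rng(1).random(len(classified)) < 0.15,
            index=classified.index,
        )
        res = stratified_enrichment(classified, flags, n_repeats=5, seed=3)
        for rep in res.repeats:
            assert len(rep.sampled_group) == len(rep.sampled_reference)
            assert len(rep.sampled_group) == rep.per_stratum_counts.sum()

    def test_identical_groups_give_zero_chi2(self):
        # both groups drawn from the same 10 genes: make the two categories
        # hold literally the same log2FCs and flags
        genes = [f"g{i}" for i in range(10)] + [f"h{i}" for i in range(10)]
        lfc = list(np.linspace(-1, 0.9, 10)) * 2
        cats = pd.DataFrame(
            {
                "category": [SU_UP] * 10 + [GENE_NOT_UP] * 10,
                "gene_log2fc": lfc,
            },
            index=pd.Index(genes, name="gene_id"),
        )
        flags = pd.Series([True] * 5 + [False] * 5, index=cats.index[:10]).reindex(
            cats.index
        )
        flags[10:] = flags[:10].to_numpy()
        res = stratified_enrichment(cats, flags.astype(bool), n_repeats=3, seed=1)
        for rep in res.repeats:
            # matched per-stratum sampling of identical distributions keeps
            # the two fractions close; with full take-all strata they match
            if rep.per_stratum_counts.sum() == 10:
                assert rep.frac_group == rep.frac_reference

    def test_planted_excess_detected(self):
        cfg = ap.SimConfig(n_multi_utr_genes=1500, n_single_utr_genes=300, seed=29)
        ds = ap.simulate_dataset(cfg)
        enh = ap.assign_enhancers(ds.truth, 0.10, 3.0, seed=29)
        from conftest import run_classification

        cats = run_classification(ds)
        res = stratified_enrichment(cats, enh, n_repeats=3, seed=29)
        fg, fr = res.mean_fractions()
        assert fg > fr

    def test_seed_determinism(self, classified):
        flags = pd.Series(
            np.random.default_rng(2).random(len(classified)) < 0.15,
            index=classified.index,
        )
        a = stratified_enrichment(classified, flags, n_repeats=2, seed=9)
        b = stratified_enrichment(classified, flags, n_repeats=2, seed=9)
        for ra, rb in zip(a.repeats, b.repeats):
            assert ra.sampled_group == rb.sampled_group
            assert ra.sampled_reference == rb.sampled_reference
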