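import numpy as np
import pytest
from hypothesis import given, strategies as st

from crosspath.enrichment import (
    BackgroundSpec,
    adjust_pvalues,
    combine_pvalues,
    filter_pathways_by_size,
    fisher_pathway_pvalue,
    run_enrichment,
)
from crosspath.errors import ConfigError, InputError
from crosspath.ingest import ingest
from crosspath.synthetic import plant_enriched_list, planted_enrichment_dump

from util import exact_hypergeom_tail, textbook_bh, textbook_holm


class TestFisherPathwayPvalue:
    def test_zero_hits_is_total_mass(self):
        assert fisher_pathway_pvalue(0, 10, 5, 100) == 1.0

    def test_saturated_degenerate_table(self):
        assert fisher_pathway_pvalue(5, 5, 5, 5) == pytest.approx(1.0)

    def test_matches_exact_tail_on_small_margins(self):
        for background in range(1, 16):
            for pathway_size in range(background + 1):
                for list_size in range(background + 1):
                    hi = min(list_size, pathway_size)
                    lo = max(0, list_size + pathway_size - background)
                    hits = np.arange(lo, hi + 1)
                    got = fisher_pathway_pvalue(hits, list_size, pathway_size, background)
                    want = [exact_hypergeom_tail(int(h), list_size, pathway_size,
                                                 background) for h in hits]
                    assert np.allclose(got, want, atol=1e-12, rtol=0)

    @given(st.integers(min_value=1, max_value=200), st.data())
    def test_monotone_nonincreasing_in_hits(self, background, data):
        pathway_size = data.draw(st.integers(0, background))
        list_size = data.draw(st.integers(0, background))
        hi = min(list_size, pathway_size)
        p = fisher_pathway_pvalue(np.arange(0, hi + 1), list_size, pathway_size,
                                  background)
        assert np.all(np.diff(np.atleast_1d(p)) <= 1e-15)

    def test_precondition_violations_name_offender(self):
        with pytest.raises(InputError, match="hits"):
            fisher_pathway_pvalue(6, 5, 10, 100)
        with pytest.raises(InputError, match="pathway_size"):
            fisher_pathway_pvalue(0, 5, 200, 100)
        with pytest.raises(InputError, match="list_size"):
            fisher_pathway_pvalue(0, 200, 5, 100)


class TestCombinePvalues:
    def test_missing_metabolite_p_passes_gene_p_through(self):
        assert combine_pvalues(None, 0.03) == 0.03
        assert combine_pvalues(0.03, None) == 0.03

    def test_both_one_gives_one(self):
        assert combine_pvalues(1.0, 1.0) == pytest.approx(1.0)

    def test_df2_closed_form_is_product(self):
        assert combine_pvalues(0.05, 0.05, df=2) == pytest.approx(0.0025, abs=1e-12)
        rng = np.random.default_rng(0)
        for p_m, p_g in rng.uniform(1e-6, 1.0, size=(200, 2)):
            assert combine_pvalues(p_m, p_g, df=2) == pytest.approx(
                p_m * p_g, abs=1e-12)

    def test_df4_is_more_conservative_than_product(self):
        assert combine_pvalues(0.05, 0.05, df=4) > 0.0025

    def test_zero_p_is_floored_not_crashing(self):
        # p=0 is floored at the smallest positive float before the log,
        # so the combination stays finite and effectively zero
        assert 0.0 <= combine_pvalues(0.0, 0.5) < 1e-300

    def test_both_absent_is_error(self):
        with pytest.raises(InputError):
            combine_pvalues(None, None)


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.04], "BH") == [0.04]
        assert adjust_pvalues([0.04], "Holm") == [0.04]

    def test_all_equal_bh_is_identity(self):
        assert adjust_pvalues([0.2] * 6, "BH") == pytest.approx([0.2] * 6)

    def test_matches_textbook_implementations(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(1, 51))
            pvals = rng.uniform(0, 1, size=n).tolist()
            assert np.allclose(adjust_pvalues(pvals, "BH"), textbook_bh(pvals),
                               atol=1e-12, rtol=0)
            assert np.allclose(adjust_pvalues(pvals, "Holm"), textbook_holm(pvals),
                               atol=1e-12, rtol=0)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_holm_dominates_raw_and_bh_preserves_order(self, pvals):
        holm = adjust_pvalues(pvals, "Holm")
        assert all(h >= p - 1e-15 for h, p in zip(holm, pvals))
        bh = adjust_pvalues(pvals, "BH")
        order_raw = np.argsort(np.argsort(pvals, kind="stable"), kind="stable")
        for i in range(len(pvals)):
            for j in range(len(pvals)):
                if pvals[i] < pvals[j]:
                    assert bh[i] <= bh[j] + 1e-15

    def test_out_of_range_is_error(self):
        with pytest.raises(InputError):
            adjust_pvalues([0.5, 1.5], "BH")


class TestSizeFilter:
    def test_boundaries_inclusive(self):
        sizes = {"too_small": 9, "lo": 10, "hi": 1000, "too_big": 1001}
        assert filter_pathways_by_size(sizes) == ["lo", "hi"]

    def test_empty_set(self):
        assert filter_pathways_by_size({}) == []


def _planted_store(dump_seed):
    dump, target = planted_enrichment_dump(seed=dump_seed)
    store, _ = ingest([dump])
    return dump, target, store


class TestRunEnrichment:
    def test_planted_pathway_attains_minimum_combined_p(self):
        hits = 0
        n_rep = 25
        for rep in range(n_rep):
            dump, target, store = _planted_store(1000 + rep)
            analytes, _ = plant_enriched_list(dump, target, 20, 5, seed=2000 + rep)
            result = run_enrichment(
                analytes, store, BackgroundSpec(metabolite={"kegg": 1000}),
                sources=["kegg"])
            top = result.table.iloc[0]
            if top.source_pathway_id == target:
                hits += 1
        assert hits >= n_rep - 1

    def test_gene_only_input_passes_gene_p_through(self, dump_factory):
        dump = dump_factory(
            "kegg",
            analytes=[(f"G{i}", "gene", f"gene{i}") for i in range(30)],
            pathways=[("P1", "pw")],
            memberships=[("P1", f"G{i}") for i in range(12)],
        )
        store, _ = ingest([dump])
        result = run_enrichment([f"G{i}" for i in range(8)], store,
                                sources=["kegg"])
        assert result.table.p_m.isna().all()
        assert (result.table.p_comb == result.table.p_g).all()

    def test_duplicates_and_order_do_not_matter(self):
        dump, target, store = _planted_store(5)
        analytes, _ = plant_enriched_list(dump, target, 15, 5, seed=6)
        spec = BackgroundSpec(metabolite={"kegg": 1000})
        a = run_enrichment(analytes, store, spec, sources=["kegg"])
        b = run_enrichment(list(reversed(analytes)) + analytes[:3], store, spec,
                           sources=["kegg"])
        assert a.table.equals(b.table)

    def test_unresolvable_list_is_error_and_partial_is_reported(self):
        dump, target, store = _planted_store(5)
        with pytest.raises(InputError):
            run_enrichment(["nope1", "nope2"], store,
                           BackgroundSpec(metabolite={"kegg": 1000}), sources=["kegg"])
        analytes, _ = plant_enriched_list(dump, target, 15, 0, seed=6)
        result = run_enrichment(analytes + ["nope1"], store,
                                BackgroundSpec(metabolite={"kegg": 1000}),
                                sources=["kegg"])
        assert result.unresolved == ["nope1"]

    def test_smpdb_not_allowed_for_enrichment(self):
        _, _, store = _planted_store(5)
        with pytest.raises(ConfigError):
            run_enrichment(["met_00001"], store, sources=["smpdb"])

    def test_background_smaller_than_pathway_is_config_error(self):
        dump, target, store = _planted_store(5)
        analytes, _ = plant_enriched_list(dump, target, 15, 0, seed=6)
        with pytest.raises(ConfigError):
            run_enrichment(analytes, store, BackgroundSpec(metabolite={"kegg": 20}),
                           sources=["kegg"])

    def test_size_filter_applied_to_tested_pathways(self):
        dump, target, store = _planted_store(5)
        analytes, _ = plant_enriched_list(dump, target, 15, 0, seed=6)
        result = run_enrichment(analytes, store,
                                BackgroundSpec(metabolite={"kegg": 1000}),
                                sources=["kegg"], min_size=31)
        assert target not in set(result.table.source_pathway_id)
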