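import pytest
from hypothesis import given, strategies as st

from crosspath.errors import InputError
from crosspath.ingest import ingest


class TestResolveName:
    def test_native_id_single_unambiguous_hit(self, toy_store):
        matches = toy_store.resolve_name("HMDB0000122")
        assert len(matches) == 1
        assert matches[0].match_kind == "native_id"
        assert not matches[0].ambiguous

    def test_shared_synonym_returns_all_matches_ambiguous(self, dump_factory):
        dump = dump_factory(
            "hmdb",
            analytes=[(f"TG{i}", "metabolite", f"TG species {i}") for i in range(5)],
            synonyms=[(f"TG{i}", "triglyceride") for i in range(5)],
        )
        store, _ = ingest([dump])
        matches = store.resolve_name("triglyceride")
        assert len(matches) == 5
        assert all(m.ambiguous for m in matches)
        rendered = [m.ramp_id.render() for m in matches]
        assert rendered == sorted(rendered)  # deterministic ordering

    def test_native_id_precedence_over_synonym(self, dump_factory):
        # "X1" is one analyte's native ID and another's synonym
        dump = dump_factory(
            "kegg",
            analytes=[("X1", "metabolite", "alpha"), ("X2", "metabolite", "beta")],
            synonyms=[("X2", "x1")],
        )
        store, _ = ingest([dump])
        matches = store.resolve_name("x1")
        assert len(matches) == 1
        assert matches[0].match_kind == "native_id"

    def test_precedence_levels_never_mix(self, toy_store):
        for query in ["glucose", "K_M1", "dextrose", "HMDB0000122"]:
            kinds = {m.match_kind for m in toy_store.resolve_name(query)}
            assert kinds <= {"native_id"} or "native_id" not in kinds

    def test_case_insensitive_with_whitespace(self, toy_store):
        assert toy_store.resolve_name("  GLUCOSE ") == toy_store.resolve_name("glucose")


class TestAnalytesForPathways:
    def test_direct_membership_lookup(self, toy_store):
        result = toy_store.analytes_for_pathways(["glycolysis"])
        kegg_rows = result.table[result.table.source_db == "kegg"]
        assert len(kegg_rows) == 3
        assert set(kegg_rows.analyte_type) == {"metabolite", "gene"}

    def test_no_match_reported_not_raised(self, toy_store):
        result = toy_store.analytes_for_pathways(["no-such-pathway"])
        assert result.table.empty
        assert result.unmatched == ["no-such-pathway"]

    def test_same_name_in_two_sources_yields_both(self, toy_store):
        result = toy_store.analytes_for_pathways(["Glycolysis"])
        assert set(result.table.source_db) == {"kegg", "wiki"}
        # brute force over fixture: 3 kegg members + 2 wiki members
        assert len(result.table) == 5

    def test_empty_input_is_error(self, toy_store):
        with pytest.raises(InputError):
            toy_store.analytes_for_pathways([])


class TestPathwaysForAnalytes:
    def test_native_id_lookup_spans_sources(self, toy_store):
        result = toy_store.pathways_for_analytes(["HMDB0000122"])
        assert set(result.table.source_db) == {"kegg", "wiki"}

    def test_mapped_but_pathway_free_analyte_reported(self, toy_store):
        result = toy_store.pathways_for_analytes(["orphan metabolite"])
        assert result.table.empty
        assert result.notes["mapped_no_pathways"] == ["orphan metabolite"]
        assert result.unmatched == []

    def test_shared_synonym_rows_flagged_ambiguous(self, dump_factory):
        dump = dump_factory(
            "kegg",
            analytes=[("A", "metabolite", "a"), ("B", "metabolite", "b")],
            synonyms=[("A", "shared"), ("B", "shared")],
            pathways=[("P1", "pw1"), ("P2", "pw2")],
            memberships=[("P1", "A"), ("P2", "B")],
        )
        store, _ = ingest([dump])
        result = store.pathways_for_analytes(["shared"])
        assert len(result.table) == 2
        assert result.table.ambiguous.all()

    @given(st.permutations(["glucose", "pyruvate", "HMDB0000122", "lactate"]))
    def test_invariant_to_input_order_and_duplicates(self, toy_store, order):
        base = toy_store.pathways_for_analytes(sorted(order))
        shuffled = toy_store.pathways_for_analytes(list(order) + [order[0]])
        assert base.table.equals(shuffled.table)


class TestReactionPartners:
    def test_gene_returns_catalyzed_metabolites(self, toy_store):
        result = toy_store.reaction_partners(["HK1"])
        assert len(result.table) == 2
        assert set(result.table.partner_type) == {"metabolite"}

    def test_metabolite_queried_back_includes_gene(self, toy_store):
        result = toy_store.reaction_partners(["glucose"])
        assert "HK1" in set(result.table.partner_name)

    def test_mixed_input_unions_both_directions(self, toy_store):
        mixed = toy_store.reaction_partners(["HK1", "glucose", "pyruvate"])
        # brute force over the fixture edge list {g1-m1, g1-m2}, both directions
        pairs = set(zip(mixed.table.query_name, mixed.table.partner_name))
        assert pairs == {("HK1", "glucose"), ("HK1", "pyruvate"),
                         ("glucose", "HK1"), ("pyruvate", "HK1")}

    def test_partnerless_analyte_reported(self, toy_store):
        result = toy_store.reaction_partners(["lactate"])
        assert result.table.empty
        assert result.notes["no_partners"] == ["lactate"]

    def test_double_hop_returns_superset_containing_start(self, toy_store):
        first = toy_store.reaction_partners(["HK1"])
        partners = list(first.table.partner_name)
        second = toy_store.reaction_partners(partners)
        assert "HK1" in set(second.table.partner_name)


class TestOntologyLookup:
    def test_term_to_metabolites_count(self, dump_factory):
        dump = dump_factory(
            "hmdb",
            analytes=[(f"M{i}", "metabolite", f"met{i}") for i in range(7)],
            ontology=[(f"M{i}", "biofluid", "blood") for i in range(5)],
        )
        store, _ = ingest([dump])
        result = store.ontology_lookup(["blood"], "ontologies_to_metabolites")
        assert len(result.table) == 5

    def test_term_matching_case_insensitive(self, toy_store):
        a = toy_store.ontology_lookup(["Blood"], "ontologies_to_metabolites")
        b = toy_store.ontology_lookup(["blood"], "ontologies_to_metabolites")
        assert a.table.drop(columns="query").equals(b.table.drop(columns="query"))

    def test_metabolite_without_assignments_reported(self, toy_store):
        result = toy_store.ontology_lookup(["lactate"], "metabolites_to_ontologies")
        assert result.table.empty
        assert result.notes["no_assignments"] == ["lactate"]

    def test_unknown_direction_is_error(self, toy_store):
        with pytest.raises(InputError):
            toy_store.ontology_lookup(["blood"], "sideways")


class TestMembershipRoundTrip:
    def test_every_edge_recoverable_from_both_queries(self, toy_store):
        for edge in toy_store.memberships:
            prec = toy_store.pathways[edge.pathway]
            arec = toy_store.analytes[edge.analyte]
            by_pathway = toy_store.analytes_for_pathways([prec.source_pathway_id])
            assert edge.analyte.render() in set(by_pathway.table.analyte_id)
            native = sorted(arec.source_ids)[0]
            by_analyte = toy_store.pathways_for_analytes([native.native_id])
            assert prec.source_pathway_id in set(by_analyte.table.pathway_source_id)


class TestExportAndPersistence:
    def test_reaction_network_nodes_and_edges(self, toy_store, tmp_path):
        result = toy_store.export_reaction_network(["HK1"])
        assert len(result.table) == 2  # g1-m1, g1-m2
        nodes = set(result.table.source_id) | set(result.table.target_id)
        assert len(nodes) == 3

    def test_duplicate_inputs_dedup_node_set(self, toy_store):
        once = toy_store.export_reaction_network(["HK1"])
        twice = toy_store.export_reaction_network(["HK1", "hk1", "glucose"])
        assert set(map(tuple, once.table.values)) <= set(map(tuple, twice.table.values))
        assert not twice.table.duplicated().any()

    def test_empty_partner_result_header_only(self, toy_store, tmp_path):
        result = toy_store.export_reaction_network(["lactate"])
        out = tmp_path / "edges.tsv"
        result.write_tsv(out)
        lines = out.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("source_id")

    def test_store_save_load_round_trip(self, toy_store, tmp_path):
        toy_store.save(tmp_path / "store")
        from crosspath.store import Store

        reloaded = Store.load(tmp_path / "store")
        assert set(reloaded.analytes) == set(toy_store.analytes)
        assert reloaded.memberships == toy_store.memberships
        assert reloaded.catalysis == toy_store.catalysis
        assert reloaded.ontology == toy_store.ontology
        for rid, rec in toy_store.analytes.items():
            assert reloaded.analytes[rid].synonyms == rec.synonyms
            assert reloaded.analytes[rid].source_ids == rec.source_ids

    def test_sql_dump_contains_schema_and_rows(self, toy_store, tmp_path):
        out = tmp_path / "dump.sql"
        toy_store.export_sql(out)
        text = out.read_text()
        assert "CREATE TABLE analyte" in text
        assert "INSERT INTO analytehaspathway" in text
        assert "glucose" in text
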