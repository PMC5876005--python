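"""In-memory harmonized store and the batch query surface.

The store is analyte-centric: genes and metabolites are first-class records
joined to pathways, reaction partners and ontology terms through edge sets.
Four batch query types are supported: analytes for pathways, pathways for
analytes, reaction-level partners, and ontology lookups in either direction.

All name matching is case-insensitive with surrounding whitespace stripped;
no fuzzy matching.  Unmatched inputs are reported in a side channel instead
of raising, so a batch never aborts on one bad row.  Row ordering in every
output is deterministic (source_db, then rendered internal ID).
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Sequence, Set, Tuple

import pandas as pd

from .errors import InputError
from .ids import RampId, SourceIdentifier
from .mapping import IdMappingTable
from .model import (
    AnalyteRecord,
    CatalysisEdge,
    MembershipEdge,
    OntologyAssignment,
    PathwayRecord,
)


def _norm(text: str) -> str:
    return text.strip().lower()


def _clean_queries(queries: Sequence[str]) -> List[str]:
    """Strip, drop blanks, deduplicate preserving first occurrence order."""
    seen, out = set(), []
    for q in queries:
        q = q.strip()
        if not q:
            continue
        key = q.lower()
        if key not in seen:
            seen.add(key)
            out.append(q)
    return out


@dataclass
class ResolvedMatch:
    ramp_id: RampId
    match_kind: str  # "native_id" | "common_name" | "synonym"
    ambiguous: bool


@dataclass
class QueryResult:
    """A tabular answer plus the side-channel report of problem inputs."""

    table: pd.DataFrame
    unmatched: List[str] = field(default_factory=list)
    notes: Dict[str, List[str]] = field(default_factory=dict)

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class Store:
    analytes: Dict[RampId, AnalyteRecord] = field(default_factory=dict)
    pathways: Dict[RampId, PathwayRecord] = field(default_factory=dict)
    memberships: Set[MembershipEdge] = field(default_factory=set)
    catalysis: Set[CatalysisEdge] = field(default_factory=set)
    ontology: Set[OntologyAssignment] = field(default_factory=set)
    mapping: IdMappingTable = field(default_factory=IdMappingTable)
    #: dump tags that contributed an identifier or membership per analyte
    analyte_sources: Dict[RampId, Set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rebuild_indexes()

    # ------------------------------------------------------------- indexes
    def rebuild_indexes(self) -> None:
        self._by_native: Dict[str, Set[RampId]] = {}
        self._by_name: Dict[str, Set[RampId]] = {}
        self._by_synonym: Dict[str, Set[RampId]] = {}
        for rid, rec in self.analytes.items():
            for sid in rec.source_ids:
                self._by_native.setdefault(_norm(sid.native_id), set()).add(rid)
            self._by_name.setdefault(_norm(rec.common_name), set()).add(rid)
            for syn in rec.synonyms:
                self._by_synonym.setdefault(_norm(syn), set()).add(rid)
        # rendered internal IDs also resolve as native-level keys
        for rid in self.analytes:
            self._by_native.setdefault(rid.render().lower(), set()).add(rid)

        self._pathway_by_name: Dict[str, Set[RampId]] = {}
        self._pathway_by_source_id: Dict[str, Set[RampId]] = {}
        for pid, prec in self.pathways.items():
            self._pathway_by_name.setdefault(_norm(prec.name), set()).add(pid)
            self._pathway_by_source_id.setdefault(_norm(prec.source_pathway_id), set()).add(pid)
            self._pathway_by_source_id.setdefault(pid.render().lower(), set()).add(pid)

        self._members_by_pathway: Dict[RampId, Set[RampId]] = {}
        self._pathways_by_analyte: Dict[RampId, Set[RampId]] = {}
        for edge in self.memberships:
            self._members_by_pathway.setdefault(edge.pathway, set()).add(edge.analyte)
            self._pathways_by_analyte.setdefault(edge.analyte, set()).add(edge.pathway)

        self._partners: Dict[RampId, Set[RampId]] = {}
        for edge in self.catalysis:
            self._partners.setdefault(edge.gene, set()).add(edge.metabolite)
            self._partners.setdefault(edge.metabolite, set()).add(edge.gene)

        self._ontology_by_metabolite: Dict[RampId, Set[OntologyAssignment]] = {}
        self._metabolites_by_term: Dict[str, Set[OntologyAssignment]] = {}
        for oa in self.ontology:
            self._ontology_by_metabolite.setdefault(oa.metabolite, set()).add(oa)
            self._metabolites_by_term.setdefault(_norm(oa.term), set()).add(oa)

    # ------------------------------------------------------------ helpers
    def pathway_members(self, pathway: RampId) -> FrozenSet[RampId]:
        return frozenset(self._members_by_pathway.get(pathway, set()))

    def pathway_member_analytes(self, pathway: RampId, analyte_type: str | None = None
                                ) -> FrozenSet[RampId]:
        members = self._members_by_pathway.get(pathway, set())
        if analyte_type is None:
            return frozenset(members)
        return frozenset(m for m in members if self.analytes[m].analyte_type == analyte_type)

    def analyte_pathways(self, analyte: RampId) -> FrozenSet[RampId]:
        return frozenset(self._pathways_by_analyte.get(analyte, set()))

    # ------------------------------------------------------------ resolve
    def resolve_name(self, query: str) -> List[ResolvedMatch]:
        """Resolve a free-text query to analytes.

        Native-identifier matches take strict precedence over common-name and
        synonym matches; within the winning level every hit is returned, each
        flagged ambiguous whenever more than one analyte matches.
        """
        key = _norm(query)
        if not key:
            return []
        native = self._by_native.get(key, set())
        if native:
            hits = sorted(native)
            return [ResolvedMatch(r, "native_id", len(hits) > 1) for r in hits]
        by_name = self._by_name.get(key, set())
        by_syn = self._by_synonym.get(key, set())
        hits = sorted(by_name | by_syn)
        ambiguous = len(hits) > 1
        return [
            ResolvedMatch(r, "common_name" if r in by_name else "synonym", ambiguous)
            for r in hits
        ]

    def _resolve_pathway(self, query: str) -> Set[RampId]:
        key = _norm(query)
        return set(self._pathway_by_name.get(key, set())) | set(
            self._pathway_by_source_id.get(key, set())
        )

    # ------------------------------------------------------------ queries
    def analytes_for_pathways(self, queries: Sequence[str]) -> QueryResult:
        """Query type 1: all member analytes of the matched pathways."""
        queries = _clean_queries(queries)
        if not queries:
            raise InputError("analytes_for_pathways: empty input list")
        rows, unmatched = [], []
        for q in queries:
            pids = self._resolve_pathway(q)
            if not pids:
                unmatched.append(q)
                continue
            for pid in sorted(pids):
                prec = self.pathways[pid]
                for aid in sorted(self._members_by_pathway.get(pid, set())):
                    arec = self.analytes[aid]
                    rows.append(
                        (prec.name, prec.source_db, aid.render(),
                         arec.analyte_type, arec.common_name)
                    )
        table = pd.DataFrame(
            rows, columns=["pathway", "source_db", "analyte_id", "analyte_type", "common_name"]
        ).drop_duplicates()
        table = table.sort_values(["source_db", "pathway", "analyte_id"]).reset_index(drop=True)
        return QueryResult(table, unmatched)

    def pathways_for_analytes(self, queries: Sequence[str]) -> QueryResult:
        """Query type 2: containing pathways per resolved analyte.

        This table is the input surface for overrepresentation analysis.
        Analytes that resolve but belong to no pathway are reported under
        ``notes["mapped_no_pathways"]``.
        """
        queries = _clean_queries(queries)
        if not queries:
            raise InputError("pathways_for_analytes: empty input list")
        rows, unmatched, no_pathways = [], [], []
        for q in queries:
            matches = self.resolve_name(q)
            if not matches:
                unmatched.append(q)
                continue
            any_pathway = False
            for m in matches:
                arec = self.analytes[m.ramp_id]
                for pid in sorted(self._pathways_by_analyte.get(m.ramp_id, set())):
                    prec = self.pathways[pid]
                    any_pathway = True
                    rows.append(
                        (q, m.ramp_id.render(), arec.common_name, prec.name,
                         prec.source_db, prec.source_pathway_id, m.ambiguous)
                    )
            if not any_pathway:
                no_pathways.append(q)
        table = pd.DataFrame(
            rows,
            columns=["query", "analyte_id", "analyte_name", "pathway_name",
                     "source_db", "pathway_source_id", "ambiguous"],
        ).drop_duplicates()
        table = table.sort_values(
            ["source_db", "analyte_id", "pathway_source_id", "query"]
        ).reset_index(drop=True)
        return QueryResult(table, unmatched, {"mapped_no_pathways": no_pathways})

    def reaction_partners(self, queries: Sequence[str]) -> QueryResult:
        """Query type 3: reaction-level partners (genes <-> metabolites)."""
        queries = _clean_queries(queries)
        if not queries:
            raise InputError("reaction_partners: empty input list")
        rows, unmatched, no_partners = [], [], []
        for q in queries:
            matches = self.resolve_name(q)
            if not matches:
                unmatched.append(q)
                continue
            found = False
            for m in matches:
                qrec = self.analytes[m.ramp_id]
                for pid in sorted(self._partners.get(m.ramp_id, set())):
                    prec = self.analytes[pid]
                    found = True
                    rows.append(
                        (q, m.ramp_id.render(), qrec.common_name, qrec.analyte_type,
                         pid.render(), prec.common_name, prec.analyte_type)
                    )
            if not found:
                no_partners.append(q)
        table = pd.DataFrame(
            rows,
            columns=["query", "query_id", "query_name", "query_type",
                     "partner_id", "partner_name", "partner_type"],
        ).drop_duplicates()
        table = table.sort_values(
            ["query_id", "partner_id", "query"]
        ).reset_index(drop=True)
        return QueryResult(table, unmatched, {"no_partners": no_partners})

    def ontology_lookup(self, queries: Sequence[str], direction: str) -> QueryResult:
        """Query type 4: metabolites -> ontology terms, or terms -> metabolites."""
        if direction not in ("metabolites_to_ontologies", "ontologies_to_metabolites"):
            raise InputError(f"unknown ontology_lookup direction {direction!r}")
        queries = _clean_queries(queries)
        if not queries:
            raise InputError("ontology_lookup: empty input list")
        rows, unmatched, no_assign = [], [], []
        if direction == "metabolites_to_ontologies":
            for q in queries:
                matches = self.resolve_name(q)
                if not matches:
                    unmatched.append(q)
                    continue
                found = False
                for m in matches:
                    for oa in sorted(self._ontology_by_metabolite.get(m.ramp_id, set())):
                        found = True
                        rows.append((q, oa.term, oa.category))
                if not found:
                    no_assign.append(q)
        else:
            for q in queries:
                assignments = self._metabolites_by_term.get(_norm(q), set())
                if not assignments:
                    unmatched.append(q)
                    continue
                for oa in sorted(assignments):
                    rows.append((q, self.analytes[oa.metabolite].common_name, oa.category))
        table = pd.DataFrame(rows, columns=["query", "match", "category"]).drop_duplicates()
        table = table.sort_values(["query", "category", "match"]).reset_index(drop=True)
        return QueryResult(table, unmatched, {"no_assignments": no_assign})

    def export_reaction_network(self, queries: Sequence[str]) -> QueryResult:
        """Edge list of gene-metabolite reaction relationships for the inputs."""
        partners = self.reaction_partners(queries)
        cols = ["source_id", "source_name", "source_type",
                "target_id", "target_name", "target_type"]
        if partners.table.empty:
            return QueryResult(pd.DataFrame(columns=cols), partners.unmatched, partners.notes)
        edges = set()
        for row in partners.table.itertuples(index=False):
            a = (row.query_id, row.query_name, row.query_type)
            b = (row.partner_id, row.partner_name, row.partner_type)
            # undirected: canonical order by ID so duplicates collapse
            edges.add((a, b) if a[0] <= b[0] else (b, a))
        table = pd.DataFrame([a + b for a, b in sorted(edges)], columns=cols)
        return QueryResult(table, partners.unmatched, partners.notes)

    # ---------------------------------------------------------------- I/O
    _TABLES = ("analytes", "source_ids", "synonyms", "sources", "pathways",
               "memberships", "catalysis", "ontology")

    def save(self, path) -> None:
        """Persist as a directory of TSV tables (text, inspectable)."""
        os.makedirs(path, exist_ok=True)
        pd.DataFrame(
            sorted(
                (r.ramp_id.render(), r.analyte_type, r.common_name)
                for r in self.analytes.values()
            ),
            columns=["ramp_id", "analyte_type", "common_name"],
        ).to_csv(os.path.join(path, "analytes.tsv"), sep="\t", index=False)
        pd.DataFrame(
            sorted(
                (r.ramp_id.render(), s.source, s.native_id)
                for r in self.analytes.values() for s in r.source_ids
            ),
            columns=["ramp_id", "source", "native_id"],
        ).to_csv(os.path.join(path, "source_ids.tsv"), sep="\t", index=False)
        pd.DataFrame(
            sorted(
                (r.ramp_id.render(), syn)
                for r in self.analytes.values() for syn in r.synonyms
            ),
            columns=["ramp_id", "synonym"],
        ).to_csv(os.path.join(path, "synonyms.tsv"), sep="\t", index=False)
        pd.DataFrame(
            sorted(
                (rid.render(), tag)
                for rid, tags in self.analyte_sources.items() for tag in tags
            ),
            columns=["ramp_id", "dump_source"],
        ).to_csv(os.path.join(path, "sources.tsv"), sep="\t", index=False)
        pd.DataFrame(
            sorted(
                (p.ramp_pathway_id.render(), p.name, p.source_db, p.source_pathway_id)
                for p in self.pathways.values()
            ),
            columns=["ramp_id", "name", "source_db", "source_pathway_id"],
        ).to_csv(os.path.join(path, "pathways.tsv"), sep="\t", index=False)
        pd.DataFrame(
            sorted((e.analyte.render(), e.pathway.render(), e.source_db)
                   for e in self.memberships),
            columns=["analyte_id", "pathway_id", "source_db"],
        ).to_csv(os.path.join(path, "memberships.tsv"), sep="\t", index=False)
        pd.DataFrame(
            sorted((e.gene.render(), e.metabolite.render()) for e in self.catalysis),
            columns=["gene_id", "metabolite_id"],
        ).to_csv(os.path.join(path, "catalysis.tsv"), sep="\t", index=False)
        pd.DataFrame(
            sorted(
                (o.metabolite.render(), o.ontology_id.render(), o.category, o.term)
                for o in self.ontology
            ),
            columns=["metabolite_id", "ontology_id", "category", "term"],
        ).to_csv(os.path.join(path, "ontology.tsv"), sep="\t", index=False)
        self.mapping.save(os.path.join(path, "id_mapping.tsv"))

    @classmethod
    def load(cls, path) -> "Store":
        if not os.path.isdir(path):
            raise InputError(f"store path does not exist or is not a directory: {path}")

        def read(name: str) -> pd.DataFrame:
            fp = os.path.join(path, name + ".tsv")
            if not os.path.exists(fp):
                raise InputError(f"store at {path} is missing table {name}.tsv")
            return pd.read_csv(fp, sep="\t", dtype=str, keep_default_na=False)

        analytes: Dict[RampId, AnalyteRecord] = {}
        for row in read("analytes").itertuples(index=False):
            rid = RampId.parse(row.ramp_id)
            analytes[rid] = AnalyteRecord(rid, row.analyte_type, row.common_name)
        for row in read("source_ids").itertuples(index=False):
            analytes[RampId.parse(row.ramp_id)].source_ids.add(
                SourceIdentifier(row.source, row.native_id)
            )
        for row in read("synonyms").itertuples(index=False):
            analytes[RampId.parse(row.ramp_id)].synonyms.add(row.synonym)
        analyte_sources: Dict[RampId, Set[str]] = {}
        for row in read("sources").itertuples(index=False):
            analyte_sources.setdefault(RampId.parse(row.ramp_id), set()).add(row.dump_source)
        pathways = {}
        for row in read("pathways").itertuples(index=False):
            pid = RampId.parse(row.ramp_id)
            pathways[pid] = PathwayRecord(pid, row.name, row.source_db, row.source_pathway_id)
        memberships = {
            MembershipEdge(RampId.parse(r.analyte_id), RampId.parse(r.pathway_id), r.source_db)
            for r in read("memberships").itertuples(index=False)
        }
        catalysis = {
            CatalysisEdge(RampId.parse(r.gene_id), RampId.parse(r.metabolite_id))
            for r in read("catalysis").itertuples(index=False)
        }
        ontology = {
            OntologyAssignment(RampId.parse(r.metabolite_id), RampId.parse(r.ontology_id),
                               r.term, r.category)
            for r in read("ontology").itertuples(index=False)
        }
        mapping_path = os.path.join(path, "id_mapping.tsv")
        mapping = IdMappingTable.load(mapping_path) if os.path.exists(mapping_path) \
            else IdMappingTable()
        return cls(analytes, pathways, memberships, catalysis, ontology,
                   mapping, analyte_sources)

    def export_sql(self, path) -> None:
        """Write a plain-text SQL dump (CREATE TABLE + INSERT) of the schema."""
        def esc(v: str) -> str:
            return "'" + str(v).replace("'", "''") + "'"

        lines = [
            "CREATE TABLE analyte (ramp_id VARCHAR(32) PRIMARY KEY, "
            "analyte_type VARCHAR(16), common_name TEXT);",
            "CREATE TABLE source (ramp_id VARCHAR(32), source VARCHAR(16), "
            "native_id VARCHAR(64));",
            "CREATE TABLE analytesynonym (ramp_id VARCHAR(32), synonym TEXT);",
            "CREATE TABLE pathway (ramp_id VARCHAR(32) PRIMARY KEY, name TEXT, "
            "source_db VARCHAR(16), source_pathway_id VARCHAR(64));",
            "CREATE TABLE analytehaspathway (analyte_id VARCHAR(32), "
            "pathway_id VARCHAR(32), source_db VARCHAR(16));",
            "CREATE TABLE catalyzed (gene_id VARCHAR(32), metabolite_id VARCHAR(32));",
            "CREATE TABLE ontology (metabolite_id VARCHAR(32), ontology_id VARCHAR(32), "
            "category VARCHAR(32), term TEXT);",
        ]
        for rec in sorted(self.analytes.values(), key=lambda r: r.ramp_id):
            lines.append(
                "INSERT INTO analyte VALUES ("
                f"{esc(rec.ramp_id.render())}, {esc(rec.analyte_type)}, "
                f"{esc(rec.common_name)});"
            )
            for sid in sorted(rec.source_ids):
                lines.append(
                    f"INSERT INTO source VALUES ({esc(rec.ramp_id.render())}, "
                    f"{esc(sid.source)}, {esc(sid.native_id)});"
                )
            for syn in sorted(rec.synonyms):
                lines.append(
                    f"INSERT INTO analytesynonym VALUES ({esc(rec.ramp_id.render())}, "
                    f"{esc(syn)});"
                )
        for prec in sorted(self.pathways.values(), key=lambda p: p.ramp_pathway_id):
            lines.append(
                "INSERT INTO pathway VALUES ("
                f"{esc(prec.ramp_pathway_id.render())}, {esc(prec.name)}, "
                f"{esc(prec.source_db)}, {esc(prec.source_pathway_id)});"
            )
        for edge in sorted(self.memberships):
            lines.append(
                f"INSERT INTO analytehaspathway VALUES ({esc(edge.analyte.render())}, "
                f"{esc(edge.pathway.render())}, {esc(edge.source_db)});"
            )
        for edge in sorted(self.catalysis):
            lines.append(
                f"INSERT INTO catalyzed VALUES ({esc(edge.gene.render())}, "
                f"{esc(edge.metabolite.render())});"
            )
        for oa in sorted(self.ontology):
            lines.append(
                f"INSERT INTO ontology VALUES ({esc(oa.metabolite.render())}, "
                f"{esc(oa.ontology_id.render())}, {esc(oa.category)}, {esc(oa.term)});"
            )
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")
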