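"""Normalized source-dump parsing and unified-ID assignment.

A *source dump* is a directory of tab-delimited tables (one header line each)
emulating one annotation database's export: analytes, identifier cross-links,
synonyms, pathways, pathway memberships, gene-metabolite catalysis pairs and
ontology assignments.

ID unification walks dumps in order.  Each analyte row contributes an
*association group*: its own (dump source, native_id) identifier plus every
cross-linked identifier.  If any group member is already mapped, the whole
group joins that internal ID; if members bridge several existing IDs, those
are merged into the lowest serial (with a tombstone recorded); otherwise a
fresh ID is minted.  Pathways and ontology terms are keyed analogously.
Synonyms never drive merging — only identifier links do, because widely
shared synonyms (e.g. "triglyceride") would collapse distinct compounds.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import pandas as pd

from .errors import DumpLoadError, DumpValidationError, InputError
from .ids import (
    PATHWAY_SOURCE_FOR_DUMP,
    RampId,
    RampIdMinter,
    SOURCE_TAGS,
    SourceIdentifier,
)
from .mapping import IdMappingTable
from .model import (
    AnalyteRecord,
    CatalysisEdge,
    MembershipEdge,
    OntologyAssignment,
    PathwayRecord,
)
from .store import Store

#: table name -> (mandatory, expected header)
DUMP_TABLES = {
    "analytes": (True, ["native_id", "analyte_type", "common_name"]),
    "id_links": (True, ["native_id", "link_source", "link_native_id"]),
    "synonyms": (True, ["native_id", "synonym"]),
    "pathways": (True, ["pathway_id", "pathway_name"]),
    "memberships": (True, ["pathway_id", "native_id"]),
    "catalysis": (False, ["gene_native_id", "metabolite_native_id"]),
    "ontology": (False, ["metabolite_native_id", "category", "term"]),
}


@dataclass
class SourceDump:
    """One normalized database export, held as pandas tables."""

    source: str
    analytes: pd.DataFrame
    id_links: pd.DataFrame
    synonyms: pd.DataFrame
    pathways: pd.DataFrame
    memberships: pd.DataFrame
    catalysis: pd.DataFrame = None  # type: ignore[assignment]
    ontology: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.source not in SOURCE_TAGS:
            raise InputError(f"unknown dump source tag {self.source!r}")
        if self.catalysis is None:
            self.catalysis = pd.DataFrame(columns=DUMP_TABLES["catalysis"][1])
        if self.ontology is None:
            self.ontology = pd.DataFrame(columns=DUMP_TABLES["ontology"][1])

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def validate(self) -> List[str]:
        """Return referential violations ("table row N: ...") without raising."""
        violations: List[str] = []
        analyte_ids = set(self.analytes["native_id"])
        pathway_ids = set(self.pathways["pathway_id"])
        if self.analytes["native_id"].duplicated().any():
            for i in self.analytes.index[self.analytes["native_id"].duplicated()]:
                violations.append(
                    f"analytes row {i + 2}: duplicate native_id "
                    f"{self.analytes.at[i, 'native_id']!r}"
                )
        checks = [
            ("id_links", "native_id", analyte_ids),
            ("synonyms", "native_id", analyte_ids),
            ("memberships", "native_id", analyte_ids),
            ("memberships", "pathway_id", pathway_ids),
            ("catalysis", "gene_native_id", analyte_ids),
            ("catalysis", "metabolite_native_id", analyte_ids),
            ("ontology", "metabolite_native_id", analyte_ids),
        ]
        for tname, col, universe in checks:
            frame = self.table(tname)
            for i, value in frame[col].items():
                if value not in universe:
                    # +2: one for the header line, one for 0-based index
                    violations.append(f"{tname} row {i + 2}: unknown {col} {value!r}")
        types = dict(zip(self.analytes["native_id"], self.analytes["analyte_type"]))
        for i, row in self.catalysis.iterrows():
            g, m = row["gene_native_id"], row["metabolite_native_id"]
            if types.get(g) not in (None, "gene"):
                violations.append(f"catalysis row {i + 2}: {g!r} is not a gene")
            if types.get(m) not in (None, "metabolite"):
                violations.append(f"catalysis row {i + 2}: {m!r} is not a metabolite")
        return violations


def parse_source_dump(path) -> SourceDump:
    """Read and validate a dump directory; raise on structural problems."""
    if not os.path.isdir(path):
        raise DumpLoadError(f"dump path does not exist or is not a directory: {path}")
    tag_file = os.path.join(path, "source.txt")
    if os.path.exists(tag_file):
        with open(tag_file, encoding="utf-8") as fh:
            source = fh.read().strip()
    else:
        source = os.path.basename(os.path.normpath(path))
    tables = {}
    for name, (mandatory, header) in DUMP_TABLES.items():
        fp = os.path.join(path, name + ".tsv")
        if not os.path.exists(fp):
            if mandatory:
                raise DumpLoadError(f"dump {path}: missing mandatory table {name}.tsv")
            tables[name] = None
            continue
        frame = pd.read_csv(fp, sep="\t", dtype=str, keep_default_na=False)
        if list(frame.columns) != header:
            raise DumpLoadError(
                f"dump {path}: {name}.tsv has header {list(frame.columns)}, "
                f"expected {header}"
            )
        tables[name] = frame
    dump = SourceDump(source=source, **tables)
    violations = dump.validate()
    if violations:
        raise DumpValidationError(violations)
    return dump


def write_source_dump(dump: SourceDump, path) -> None:
    """Write a dump directory in the normalized format (round-trips with parse)."""
    os.makedirs(path, exist_ok=True)
    with open(os.path.join(path, "source.txt"), "w", encoding="utf-8") as fh:
        fh.write(dump.source + "\n")
    for name in DUMP_TABLES:
        dump.table(name).to_csv(os.path.join(path, name + ".tsv"), sep="\t", index=False)


@dataclass
class ResolutionReport:
    """Per-dump accounting of how association groups resolved."""

    source: str
    new_ids: int = 0
    matched: int = 0
    merges: List[Tuple[str, str]] = field(default_factory=list)  # (retired, survivor)


def _resolve_group(group: Set[SourceIdentifier], kind: str, mapping: IdMappingTable,
                   minter: RampIdMinter, report: ResolutionReport) -> RampId:
    """Match-or-mint one association group; merge when it bridges existing IDs."""
    existing = sorted({mapping.forward[s] for s in group if s in mapping.forward})
    for rid in existing:
        if rid.kind != kind:
            raise DumpValidationError(
                [f"{report.source}: identifiers {sorted(str(s) for s in group)} "
                 f"claimed as {kind} but already mapped as {rid.kind}"]
            )
    if not existing:
        rid = minter.mint(kind)
        mapping.assign(rid, group)
        report.new_ids += 1
        return rid
    survivor = existing[0]
    for retired in existing[1:]:
        mapping.merge(survivor, retired)
        report.merges.append((retired.render(), survivor.render()))
    mapping.assign(survivor, group)
    report.matched += 1
    return survivor


def ontology_term_identifier(category: str, term: str) -> SourceIdentifier:
    """Ontology terms harmonize on (category, case-folded term) across dumps."""
    return SourceIdentifier("custom", f"ontology:{category}:{term.strip().lower()}")


def assign_ramp_ids(
    dumps: Sequence[SourceDump],
    existing: IdMappingTable | None = None,
) -> Tuple[IdMappingTable, List[ResolutionReport]]:
    """Assign unified IDs to every entity across dumps, in dump order.

    Returns the updated mapping table and one resolution report per dump.
    Serial assignment is reproducible: analytes are processed before pathways
    before ontology terms, each in file row order.
    """
    mapping = existing if existing is not None else IdMappingTable()
    minter = RampIdMinter()
    for rid in mapping.reverse:
        minter.advance_past(rid)
    reports: List[ResolutionReport] = []
    for dump in dumps:
        report = ResolutionReport(dump.source)
        links_by_native: Dict[str, Set[SourceIdentifier]] = {}
        for row in dump.id_links.itertuples(index=False):
            links_by_native.setdefault(row.native_id, set()).add(
                SourceIdentifier(row.link_source, row.link_native_id)
            )
        for row in dump.analytes.itertuples(index=False):
            kind = "compound" if row.analyte_type == "metabolite" else "gene"
            group = {SourceIdentifier(dump.source, row.native_id)}
            group |= links_by_native.get(row.native_id, set())
            _resolve_group(group, kind, mapping, minter, report)
        for row in dump.pathways.itertuples(index=False):
            group = {SourceIdentifier(dump.source, row.pathway_id)}
            _resolve_group(group, "pathway", mapping, minter, report)
        seen_terms = set()
        for row in dump.ontology.itertuples(index=False):
            sid = ontology_term_identifier(row.category, row.term)
            if sid in seen_terms:
                continue
            seen_terms.add(sid)
            _resolve_group({sid}, "ontology", mapping, minter, report)
        reports.append(report)
    return mapping, reports


def build_store(dumps: Sequence[SourceDump], mapping: IdMappingTable) -> Store:
    """Re-key all dump rows to unified IDs and assemble the deduplicated store."""
    analytes: Dict[RampId, AnalyteRecord] = {}
    pathways: Dict[RampId, PathwayRecord] = {}
    memberships: Set[MembershipEdge] = set()
    catalysis: Set[CatalysisEdge] = set()
    ontology: Set[OntologyAssignment] = set()
    analyte_sources: Dict[RampId, Set[str]] = {}

    def analyte_ramp(dump: SourceDump, native_id: str) -> RampId:
        rid = mapping.lookup(SourceIdentifier(dump.source, native_id))
        if rid is None:
            raise InputError(
                f"{dump.source}:{native_id} has no assigned ID; run assign_ramp_ids first"
            )
        return rid

    for dump in dumps:
        for row in dump.analytes.itertuples(index=False):
            rid = analyte_ramp(dump, row.native_id)
            atype = row.analyte_type
            if rid not in analytes:
                analytes[rid] = AnalyteRecord(rid, atype, row.common_name)
            else:
                rec = analytes[rid]
                if rec.analyte_type != atype:
                    raise DumpValidationError(
                        [f"{dump.source}:{row.native_id} claimed as {atype} but "
                         f"{rid.render()} is a {rec.analyte_type}"]
                    )
                if row.common_name != rec.common_name:
                    rec.synonyms.add(row.common_name)
            analytes[rid].source_ids.update(
                {SourceIdentifier(dump.source, row.native_id)}
                | {s for s in mapping.reverse[rid]}
            )
            analyte_sources.setdefault(rid, set()).add(dump.source)
        for row in dump.synonyms.itertuples(index=False):
            analytes[analyte_ramp(dump, row.native_id)].synonyms.add(row.synonym)
        if dump.pathways.shape[0] and dump.source not in PATHWAY_SOURCE_FOR_DUMP:
            raise DumpValidationError(
                [f"{dump.source}: dumps with this tag may not contribute pathways"]
            )
        source_db = PATHWAY_SOURCE_FOR_DUMP.get(dump.source, "")
        for row in dump.pathways.itertuples(index=False):
            pid = mapping.lookup(SourceIdentifier(dump.source, row.pathway_id))
            if pid not in pathways:
                pathways[pid] = PathwayRecord(pid, row.pathway_name, source_db, row.pathway_id)
        for row in dump.memberships.itertuples(index=False):
            pid = mapping.lookup(SourceIdentifier(dump.source, row.pathway_id))
            memberships.add(MembershipEdge(analyte_ramp(dump, row.native_id), pid, source_db))
        for row in dump.catalysis.itertuples(index=False):
            catalysis.add(
                CatalysisEdge(
                    analyte_ramp(dump, row.gene_native_id),
                    analyte_ramp(dump, row.metabolite_native_id),
                )
            )
        for row in dump.ontology.itertuples(index=False):
            oid = mapping.lookup(ontology_term_identifier(row.category, row.term))
            ontology.add(
                OntologyAssignment(
                    analyte_ramp(dump, row.metabolite_native_id), oid,
                    row.term.strip(), row.category,
                )
            )
    return Store(analytes, pathways, memberships, catalysis, ontology,
                 mapping, analyte_sources)


def ingest(dumps: Sequence[SourceDump],
           existing: IdMappingTable | None = None) -> Tuple[Store, List[ResolutionReport]]:
    """Convenience wrapper: assign IDs, then build the store."""
    mapping, reports = assign_ramp_ids(dumps, existing)
    return build_store(dumps, mapping), reports
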