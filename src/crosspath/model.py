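"""Harmonized record types held by a store."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Set

from .errors import InputError
from .ids import PATHWAY_SOURCES, RampId, SourceIdentifier


@dataclass
class AnalyteRecord:
    """A harmonized gene or metabolite with all of its linked source identifiers."""

    ramp_id: RampId
    analyte_type: str  # "metabolite" | "gene"
    common_name: str
    synonyms: Set[str] = field(default_factory=set)
    source_ids: Set[SourceIdentifier] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.analyte_type not in ("metabolite", "gene"):
            raise InputError(f"unknown analyte_type {self.analyte_type!r}")
        expected = "compound" if self.analyte_type == "metabolite" else "gene"
        if self.ramp_id.kind != expected:
            raise InputError(
                f"analyte_type {self.analyte_type} requires RampId kind {expected}, "
                f"got {self.ramp_id.kind}"
            )


@dataclass
class PathwayRecord:
    """A pathway as asserted by one source database."""

    ramp_pathway_id: RampId
    name: str
    source_db: str
    source_pathway_id: str

    def __post_init__(self) -> None:
        if self.ramp_pathway_id.kind != "pathway":
            raise InputError("PathwayRecord requires a pathway-kind RampId")
        if self.source_db not in PATHWAY_SOURCES:
            raise InputError(f"unknown pathway source_db {self.source_db!r}")


@dataclass(frozen=True, order=True)
class MembershipEdge:
    """Asserts that an analyte belongs to a pathway, per source."""

    analyte: RampId
    pathway: RampId
    source_db: str


@dataclass(frozen=True, order=True)
class CatalysisEdge:
    """A gene–metabolite pair participating in the same reaction (undirected)."""

    gene: RampId
    metabolite: RampId


@dataclass(frozen=True, order=True)
class OntologyAssignment:
    """Links a metabolite to an ontology term (biofluid, cellular location, ...)."""

    metabolite: RampId
    ontology_id: RampId
    term: str
    category: str
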