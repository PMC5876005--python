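"""Internal unified identifiers and their source-database counterparts.

Harmonization assigns every analyte, pathway and ontology term one internal
ID rendered as a fixed prefix plus a zero-padded nine-digit serial
(``RAMP_C``/``RAMP_G``/``RAMP_P``/``RAMP_OL`` for compounds, genes, pathways
and ontology terms respectively).  These IDs act as stable join keys across
sources; user-facing answers are keyed by them but described by names.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InputError, SerialOverflowError

#: Source tags a native identifier may carry.
SOURCE_TAGS = ("hmdb", "kegg", "reactome", "wiki", "chebi", "pubchem", "uniprot", "custom")

#: Source databases a pathway may come from.
PATHWAY_SOURCES = ("kegg", "reactome", "wiki", "smpdb")

#: Dump tags allowed to contribute pathways, and the pathway source label
#: each one yields.  An "hmdb" dump carries SMPDB pathways.
PATHWAY_SOURCE_FOR_DUMP = {"hmdb": "smpdb", "kegg": "kegg", "reactome": "reactome", "wiki": "wiki"}

KINDS = ("compound", "gene", "pathway", "ontology")
KIND_PREFIX = {"compound": "RAMP_C", "gene": "RAMP_G", "pathway": "RAMP_P", "ontology": "RAMP_OL"}
MAX_SERIAL = 999_999_999

ONTOLOGY_CATEGORIES = ("biofluid", "cellular_location", "origin", "tissue")


@dataclass(frozen=True, order=True)
class SourceIdentifier:
    """A (source-database tag, native ID) pair — the atomic unit of harmonization."""

    source: str
    native_id: str

    def __post_init__(self) -> None:
        if self.source not in SOURCE_TAGS:
            raise InputError(f"unknown source tag {self.source!r}")
        if not self.native_id:
            raise InputError("native_id must be nonempty")
        if "\t" in self.native_id or "\n" in self.native_id:
            raise InputError(f"native_id {self.native_id!r} contains tab/newline")

    def __str__(self) -> str:  # pragma: no cover - display helper
        return f"{self.source}:{self.native_id}"


@dataclass(frozen=True, order=True)
class RampId:
    """Internal unified ID: a kind plus a positive serial below one billion."""

    kind: str
    serial: int

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise InputError(f"unknown RampId kind {self.kind!r}")
        if not (1 <= self.serial <= MAX_SERIAL):
            raise InputError(f"serial {self.serial} outside 1..{MAX_SERIAL}")

    def render(self) -> str:
        return f"{KIND_PREFIX[self.kind]}{self.serial:09d}"

    @classmethod
    def parse(cls, text: str) -> "RampId":
        for kind, prefix in KIND_PREFIX.items():
            # RAMP_OL shares the RAMP_ prefix family; test longest first
            if text.startswith(prefix) and len(text) == len(prefix) + 9:
                tail = text[len(prefix):]
                if tail.isdigit():
                    # compound prefix RAMP_C would also match RAMP_OL-rendered
                    # strings only if digits followed, which they cannot
                    return cls(kind, int(tail))
        raise InputError(f"not a rendered RampId: {text!r}")

    def __str__(self) -> str:  # pragma: no cover - display helper
        return self.render()


@dataclass
class RampIdMinter:
    """Issues serials sequentially per kind, starting at 1."""

    counters: dict = field(default_factory=lambda: {k: 0 for k in KINDS})

    def mint(self, kind: str) -> RampId:
        if kind not in KINDS:
            raise InputError(f"unknown RampId kind {kind!r}")
        if self.counters[kind] >= MAX_SERIAL:
            raise SerialOverflowError(f"serial space exhausted for kind {kind!r}")
        self.counters[kind] += 1
        return RampId(kind, self.counters[kind])

    def advance_past(self, ramp_id: RampId) -> None:
        """Ensure future serials do not collide with an existing ID."""
        if ramp_id.serial > self.counters[ramp_id.kind]:
            self.counters[ramp_id.kind] = ramp_id.serial
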