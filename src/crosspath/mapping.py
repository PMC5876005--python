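"""The one-to-many table relating internal unified IDs to source identifiers.

Each source identifier maps to exactly one internal ID; each internal ID
covers one or more source identifiers.  When a later association group
bridges two pre-existing IDs, the groups are merged into the lowest serial
and the retired ID is recorded as a tombstone.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Set, Tuple

import pandas as pd

from .errors import InputError
from .ids import RampId, SourceIdentifier


@dataclass
class IdMappingTable:
    """Bidirectional (RampId <-> SourceIdentifier) mapping with merge log."""

    forward: Dict[SourceIdentifier, RampId] = field(default_factory=dict)
    reverse: Dict[RampId, Set[SourceIdentifier]] = field(default_factory=dict)
    tombstones: List[Tuple[RampId, RampId]] = field(default_factory=list)  # (retired, survivor)

    def lookup(self, sid: SourceIdentifier) -> RampId | None:
        return self.forward.get(sid)

    def assign(self, ramp_id: RampId, sids: Iterable[SourceIdentifier]) -> None:
        members = self.reverse.setdefault(ramp_id, set())
        for sid in sids:
            existing = self.forward.get(sid)
            if existing is not None and existing != ramp_id:
                raise InputError(
                    f"source identifier {sid} already mapped to {existing.render()}"
                )
            self.forward[sid] = ramp_id
            members.add(sid)

    def merge(self, survivor: RampId, retired: RampId) -> None:
        """Fold ``retired`` into ``survivor`` and record a tombstone."""
        if survivor == retired:
            return
        if survivor.kind != retired.kind:
            raise InputError("cannot merge RampIds of different kinds")
        for sid in self.reverse.pop(retired, set()):
            self.forward[sid] = survivor
            self.reverse.setdefault(survivor, set()).add(sid)
        self.tombstones.append((retired, survivor))

    def ramp_ids(self, kind: str | None = None) -> List[RampId]:
        ids = self.reverse.keys()
        if kind is not None:
            ids = (r for r in ids if r.kind == kind)
        return sorted(ids)

    def __len__(self) -> int:
        return len(self.forward)

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        rows = [
            (ramp.render(), sid.source, sid.native_id)
            for ramp, sids in self.reverse.items()
            for sid in sorted(sids)
        ]
        frame = pd.DataFrame(rows, columns=["ramp_id", "source", "native_id"])
        return frame.sort_values(["ramp_id", "source", "native_id"]).reset_index(drop=True)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "IdMappingTable":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        expected = ["ramp_id", "source", "native_id"]
        if list(frame.columns) != expected:
            raise InputError(f"mapping file {path}: expected columns {expected}")
        table = cls()
        for row in frame.itertuples(index=False):
            table.assign(RampId.parse(row.ramp_id), [SourceIdentifier(row.source, row.native_id)])
        return table
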