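"""Database-content diagnostics: cross-source Venn counts, pathway
promiscuity, and the all-pairs pathway-overlap matrix.

These mirror the sanity checks a curator runs after integrating several
annotation sources: how much the sources share, which analytes sit in
suspiciously many pathways, and how redundant the pathway collection is.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Tuple

import pandas as pd

from .clustering import OverlapMatrix, pairwise_overlaps, pathway_analyte_sets
from .errors import InputError
from .ids import PATHWAY_SOURCES
from .store import Store


@dataclass
class SourceOverlapReport:
    """Exact Venn-cell decomposition of analytes over contributing sources."""

    analyte_type: str
    cells: Dict[FrozenSet[str], int]
    total: int
    unique_percent: Dict[str, float]  # per source: % of its analytes unique to it

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("+".join(sorted(cell)), count)
            for cell, count in sorted(self.cells.items(), key=lambda kv: sorted(kv[0]))
        ]
        return pd.DataFrame(rows, columns=["source_set", "count"])


def source_overlap_counts(store: Store, analyte_type: str,
                          pathway_mapped_only: bool = False) -> SourceOverlapReport:
    """Count analytes per exact source subset.

    An analyte belongs to a source if that source contributed any identifier
    or membership for it.  With ``pathway_mapped_only`` the census is
    restricted to analytes that belong to at least one pathway.
    """
    if analyte_type not in ("metabolite", "gene"):
        raise InputError(f"unknown analyte_type {analyte_type!r}")
    if not store.analyte_sources:
        raise InputError("store has no recorded source contributions")
    cells: Dict[FrozenSet[str], int] = {}
    per_source_total: Dict[str, int] = {}
    per_source_unique: Dict[str, int] = {}
    total = 0
    for rid, rec in store.analytes.items():
        if rec.analyte_type != analyte_type:
            continue
        if pathway_mapped_only and not store.analyte_pathways(rid):
            continue
        sources = frozenset(store.analyte_sources.get(rid, set()))
        if not sources:
            continue
        total += 1
        cells[sources] = cells.get(sources, 0) + 1
        for s in sources:
            per_source_total[s] = per_source_total.get(s, 0) + 1
            if len(sources) == 1:
                per_source_unique[s] = per_source_unique.get(s, 0) + 1
    unique_percent = {
        s: 100.0 * per_source_unique.get(s, 0) / n
        for s, n in per_source_total.items()
    }
    return SourceOverlapReport(analyte_type, cells, total, unique_percent)


def pathway_promiscuity(store: Store) -> pd.DataFrame:
    """Per-analyte pathway counts, split by pathway source, descending by total.

    Analytes in no pathway appear with total 0 at the bottom — promiscuous
    analytes at the top are the ones that complicate enrichment
    interpretation.
    """
    source_cols = [s for s in PATHWAY_SOURCES
                   if any(p.source_db == s for p in store.pathways.values())]
    rows = []
    for rid, rec in store.analytes.items():
        counts = {s: 0 for s in source_cols}
        for pid in store.analyte_pathways(rid):
            src = store.pathways[pid].source_db
            if src in counts:
                counts[src] += 1
        rows.append(
            (rid.render(), rec.common_name, rec.analyte_type,
             *[counts[s] for s in source_cols], sum(counts.values()))
        )
    frame = pd.DataFrame(
        rows,
        columns=["analyte_id", "analyte_name", "analyte_type", *source_cols, "total"],
    )
    return frame.sort_values(
        ["total", "analyte_id"], ascending=[False, True]
    ).reset_index(drop=True)


def all_pairs_overlap(store: Store, basis: str = "metabolites"
                      ) -> Tuple[OverlapMatrix, pd.DataFrame]:
    """Jaccard overlap for every stored pathway pair, across all sources.

    Pathways are block-ordered by source database for heatmap export.  The
    long-form frame holds one row per unordered pair (including self-pairs
    on the diagonal).
    """
    ordered = sorted(
        store.pathways,
        key=lambda pid: (PATHWAY_SOURCES.index(store.pathways[pid].source_db), pid),
    )
    sets = pathway_analyte_sets(store, ordered, basis)
    matrix = pairwise_overlaps(sets, basis)
    rows = []
    for i, a in enumerate(ordered):
        for j in range(i, len(ordered)):
            b = ordered[j]
            rows.append(
                (store.pathways[a].name, store.pathways[b].name,
                 store.pathways[a].source_db, store.pathways[b].source_db,
                 float(matrix.matrix[i, j]))
            )
    frame = pd.DataFrame(
        rows, columns=["pathway_a", "pathway_b", "source_a", "source_b", "overlap"]
    )
    return matrix, frame
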