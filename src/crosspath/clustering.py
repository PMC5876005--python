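"""Fuzzy multiple-linkage clustering of enriched pathways by analyte overlap.

Redundant pathways — nested hierarchies within one source, near-duplicates
across sources — clutter enrichment output.  This module groups them:

1. Jaccard overlap is computed for every pathway pair over their analyte
   member sets.
2. Pathways overlapping at least ``seed_overlap_threshold`` with at least
   ``min_seed_neighbors`` other pathways become cluster *seeds* (medoids).
3. Every pathway joins every seed it overlaps at
   ``member_overlap_threshold`` or more — one pathway may belong to several
   clusters.
4. Cluster pairs are scored with the same Jaccard formula over shared
   member pathways; the top-scoring pair is merged while its score exceeds
   ``merge_threshold``.

Tie-breaking and labeling are deterministic: equal-score pairs merge in
lexicographic label order, merged clusters keep the smaller label index, and
labels are ``cluster_<k>`` in order of seed discovery.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .store import Store

BASES = ("metabolites", "genes", "pooled")
_BASIS_TYPE = {"metabolites": "metabolite", "genes": "gene", "pooled": None}


@dataclass
class ClusterParams:
    """Thresholds governing seed discovery, membership and merging."""

    seed_overlap_threshold: float = 0.30
    min_seed_neighbors: int = 2
    member_overlap_threshold: float = 0.30
    merge_threshold: float = 0.30

    def __post_init__(self) -> None:
        for name in ("seed_overlap_threshold", "member_overlap_threshold",
                     "merge_threshold"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ConfigError(f"{name}={v} outside (0, 1]")
        if self.min_seed_neighbors < 1:
            raise ConfigError("min_seed_neighbors must be >= 1")

    @classmethod
    def metabolite_preset(cls) -> "ClusterParams":
        """Preset for metabolite-only enrichment runs."""
        return cls(0.2, 2, 0.2, 0.75)

    @classmethod
    def combined_preset(cls) -> "ClusterParams":
        """Preset for combined gene+metabolite enrichment runs."""
        return cls(0.2, 2, 0.2, 0.5)


def overlap_score(analytes_m: Set, analytes_n: Set) -> float:
    """Jaccard index |intersection| / |union|; 0 when either set is empty."""
    if not analytes_m or not analytes_n:
        return 0.0
    inter = len(analytes_m & analytes_n)
    return inter / (len(analytes_m) + len(analytes_n) - inter)


@dataclass
class OverlapMatrix:
    """Symmetric all-pairs Jaccard matrix over labeled pathways."""

    labels: List
    matrix: np.ndarray
    basis: str

    def score(self, a, b) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])


def pathway_analyte_sets(store: Store, pathway_ids: Sequence, basis: str
                         ) -> Dict[object, FrozenSet]:
    """Member sets per pathway under the chosen analyte basis."""
    if basis not in BASES:
        raise ConfigError(f"unknown basis {basis!r}; allowed: {BASES}")
    atype = _BASIS_TYPE[basis]
    return {pid: store.pathway_member_analytes(pid, atype) for pid in pathway_ids}


def pairwise_overlaps(pathway_sets: Mapping[object, Set], basis: str = "pooled"
                      ) -> OverlapMatrix:
    """All-pairs Jaccard overlaps; diagonal is 1 for nonempty pathways."""
    labels = list(pathway_sets)
    n = len(labels)
    matrix = np.zeros((n, n))
    sets = [pathway_sets[l] for l in labels]
    for i in range(n):
        matrix[i, i] = 1.0 if sets[i] else 0.0
        for j in range(i + 1, n):
            matrix[i, j] = matrix[j, i] = overlap_score(sets[i], sets[j])
    return OverlapMatrix(labels, matrix, basis)


def identify_seeds(matrix: OverlapMatrix, params: ClusterParams) -> List:
    """Pathways overlapping enough neighbors strongly enough, in label order."""
    seeds = []
    for i, label in enumerate(matrix.labels):
        neighbors = sum(
            1
            for j in range(len(matrix.labels))
            if j != i and matrix.matrix[i, j] >= params.seed_overlap_threshold
        )
        if neighbors >= params.min_seed_neighbors:
            seeds.append(label)
    return seeds


@dataclass
class PathwayCluster:
    """A labeled group of pathways anchored on a seed; members may be shared."""

    label: str
    seed: object
    members: Set = field(default_factory=set)
    provenance: List[str] = field(default_factory=list)

    @property
    def index(self) -> int:
        return int(self.label.rsplit("_", 1)[1])


def build_initial_clusters(seeds: Sequence, matrix: OverlapMatrix,
                           params: ClusterParams) -> List[PathwayCluster]:
    """One cluster per seed, holding every pathway within the member threshold."""
    clusters = []
    for k, seed in enumerate(seeds, start=1):
        i = matrix.labels.index(seed)
        members = {
            matrix.labels[j]
            for j in range(len(matrix.labels))
            if matrix.matrix[i, j] >= params.member_overlap_threshold and j != i
        }
        members.add(seed)
        clusters.append(PathwayCluster(f"cluster_{k}", seed, members))
    return clusters


def merge_clusters(
    clusters: Sequence[PathwayCluster],
    params: ClusterParams,
    names: Mapping | None = None,
) -> Tuple[List[PathwayCluster], List[Tuple[str, str, float]]]:
    """Iteratively merge the top-overlapping cluster pair above the threshold.

    Cluster-pair overlap reuses the Jaccard formula with members identified
    by pathway *name* (``names`` maps member keys to names; identity when
    omitted), so the same pathway reported by two sources counts as shared.
    Returns the final clusters and a merge log of
    (absorbed label, surviving label, score).
    """
    def name_set(cluster: PathwayCluster) -> FrozenSet:
        if names is None:
            return frozenset(cluster.members)
        return frozenset(names[m] for m in cluster.members)

    live: List[PathwayCluster] = [
        PathwayCluster(c.label, c.seed, set(c.members), list(c.provenance))
        for c in clusters
    ]
    log: List[Tuple[str, str, float]] = []
    while len(live) > 1:
        best: Tuple[float, Tuple[str, str]] | None = None
        best_pair: Tuple[int, int] | None = None
        for i in range(len(live)):
            for j in range(i + 1, len(live)):
                score = overlap_score(name_set(live[i]), name_set(live[j]))
                pair_labels = tuple(sorted((live[i].label, live[j].label)))
                key = (-score, pair_labels)
                if best is None or key < best:
                    best = key
                    best_pair = (i, j)
        score = -best[0]
        if score <= params.merge_threshold:
            break
        i, j = best_pair
        keep, absorb = (live[i], live[j]) if live[i].index < live[j].index \
            else (live[j], live[i])
        keep.members |= absorb.members
        keep.provenance.append(
            f"absorbed {absorb.label} (seed {absorb.seed}) at overlap {score:.4f}"
        )
        log.append((absorb.label, keep.label, score))
        live.remove(absorb)
    return live, log


def cluster_pathways(
    pathway_sets: Mapping[object, Set],
    params: ClusterParams,
    names: Mapping | None = None,
) -> Tuple[List[PathwayCluster], List[Tuple[str, str, float]], Dict[object, List[str]]]:
    """Full pipeline over member sets; returns clusters, merge log, and
    per-pathway cluster labels (empty list = singleton)."""
    matrix = pairwise_overlaps(pathway_sets)
    seeds = identify_seeds(matrix, params)
    initial = build_initial_clusters(seeds, matrix, params)
    final, log = merge_clusters(initial, params, names)
    labels: Dict[object, List[str]] = {key: [] for key in pathway_sets}
    for cluster in final:
        for member in cluster.members:
            labels[member].append(cluster.label)
    for key in labels:
        labels[key].sort(key=lambda lab: int(lab.rsplit("_", 1)[1]))
    return final, log, labels


def cluster_enrichment_results(
    enrichment_table: pd.DataFrame,
    store: Store,
    params: ClusterParams | None = None,
    basis: str = "pooled",
) -> Tuple[pd.DataFrame, List[PathwayCluster], List[Tuple[str, str, float]]]:
    """Annotate an enrichment table with cluster labels.

    Each enriched pathway receives zero or more semicolon-separated labels in
    a ``cluster_labels`` column; pathways in no cluster are labeled
    ``singleton``.  An empty table round-trips to an empty annotated table.
    """
    params = params if params is not None else ClusterParams()
    table = enrichment_table.copy()
    if table.empty:
        table["cluster_labels"] = pd.Series(dtype=str)
        return table, [], []
    keys, names = [], {}
    for row in table.itertuples(index=False):
        key = (row.source_db, row.source_pathway_id)
        keys.append(key)
        names[key] = row.pathway_name.strip().lower()
    by_source_id = {
        (rec.source_db, rec.source_pathway_id): pid
        for pid, rec in store.pathways.items()
    }
    missing = [k for k in keys if k not in by_source_id]
    if missing:
        raise InputError(f"enrichment rows not found in store: {missing[:5]}")
    pid_for = {k: by_source_id[k] for k in keys}
    sets_by_pid = pathway_analyte_sets(store, [pid_for[k] for k in keys], basis)
    pathway_sets = {k: sets_by_pid[pid_for[k]] for k in keys}
    final, log, labels = cluster_pathways(pathway_sets, params, names)
    table["cluster_labels"] = [
        ";".join(labels[k]) if labels[k] else "singleton" for k in keys
    ]
    return table, final, log
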