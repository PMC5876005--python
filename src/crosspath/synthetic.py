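"""Seeded synthetic source dumps with known ground truth.

The generator emulates the structural features of real multi-source
annotation data that exercise the rest of the package: several sources
holding different native identifiers for the same underlying analyte
(cross-linked through a shared reference identifier), nested Reactome-style
pathway hierarchies with high mutual overlap, pathways of widely varying
size, promiscuous analytes sitting in many pathways, widely shared synonyms,
and analyte lists with a planted enriched pathway.  A manifest records the
ground truth (true analyte partition, pathway nesting, planted features) so
tests can treat it as an oracle.  Identical config and seed produce
byte-identical dumps.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .ingest import DUMP_TABLES, SourceDump

DEFAULT_SOURCE_TAGS = ("kegg", "reactome", "wiki", "hmdb")


@dataclass
class SynthConfig:
    """Parameters of the synthetic multi-source universe."""

    seed: int = 0
    n_sources: int = 3
    n_metabolites: int = 200  # per source
    n_genes: int = 200  # per source
    cross_source_share_fraction: float = 0.3
    n_pathways: int = 30  # per source
    pathway_size_min: int = 10
    pathway_size_max: int = 60
    hierarchy_depth: int = 2
    synonym_collision_count: int = 3
    promiscuous_analyte_count: int = 2

    def __post_init__(self) -> None:
        for name in ("n_sources", "n_metabolites", "n_genes", "n_pathways"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not (0.0 <= self.cross_source_share_fraction <= 1.0):
            raise ConfigError("cross_source_share_fraction outside [0, 1]")
        if self.pathway_size_min < 1 or self.pathway_size_max < self.pathway_size_min:
            raise ConfigError("invalid pathway size range")
        if self.pathway_size_max > self.n_metabolites + self.n_genes:
            raise ConfigError("pathway_size_max exceeds the per-source analyte pool")
        if self.n_sources > len(DEFAULT_SOURCE_TAGS):
            raise ConfigError(f"at most {len(DEFAULT_SOURCE_TAGS)} sources supported")
        if self.hierarchy_depth < 0 or self.synonym_collision_count < 0 \
                or self.promiscuous_analyte_count < 0:
            raise ConfigError("counts must be nonnegative")


def _source_tags(config: SynthConfig) -> List[str]:
    return list(DEFAULT_SOURCE_TAGS[: config.n_sources])


def generate_dumps(config: SynthConfig) -> Tuple[List[SourceDump], pd.DataFrame]:
    """Build one dump per source plus a ground-truth manifest.

    Shared analytes carry a cross-link to a common reference identifier
    (chebi for metabolites, uniprot for genes), so the true co-reference
    partition equals the connected components of the pooled link graph by
    construction.  Manifest rows are (truth_type, key, value).
    """
    rng = np.random.default_rng(config.seed)
    tags = _source_tags(config)
    n_shared_m = round(config.cross_source_share_fraction * config.n_metabolites)
    n_shared_g = round(config.cross_source_share_fraction * config.n_genes)

    manifest_rows: List[Tuple[str, str, str]] = []
    dumps: List[SourceDump] = []
    for s_idx, tag in enumerate(tags):
        analyte_rows, link_rows, synonym_rows = [], [], []
        met_ids: List[str] = []
        gene_ids: List[str] = []
        for kind, n_total, n_shared, ref_source, ref_prefix, id_list in (
            ("metabolite", config.n_metabolites, n_shared_m, "chebi", "CHEBI:5", met_ids),
            ("gene", config.n_genes, n_shared_g, "uniprot", "UP:7", gene_ids),
        ):
            for i in range(n_total):
                shared = i < n_shared
                native = f"{tag.upper()}_{kind[0].upper()}{i:05d}"
                id_list.append(native)
                if shared:
                    true_key = f"shared_{kind}_{i:05d}"
                    name = f"{kind}_{i:05d}"
                    link_rows.append((native, ref_source, f"{ref_prefix}{i:05d}"))
                else:
                    true_key = f"{tag}_{kind}_{i:05d}"
                    name = f"{tag}_{kind}_{i:05d}"
                analyte_rows.append((native, kind, name))
                synonym_rows.append((native, f"syn_{native.lower()}"))
                manifest_rows.append(("analyte_partition", f"{tag}:{native}", true_key))
        # widely shared synonyms planted on several metabolites
        for j in range(config.synonym_collision_count):
            carriers = [met_ids[(j * 7 + k) % len(met_ids)] for k in range(3)]
            for native in sorted(set(carriers)):
                synonym_rows.append((native, f"shared_synonym_{j}"))
                manifest_rows.append(
                    ("synonym_collision", f"shared_synonym_{j}", f"{tag}:{native}")
                )

        pool = met_ids + gene_ids
        pathway_rows, membership_rows = [], []
        members_of: Dict[str, List[str]] = {}
        parents: List[str] = []
        p_idx = 0
        while p_idx < config.n_pathways:
            pw_id = f"{tag.upper()}_PW{p_idx:04d}"
            nestable = (
                config.hierarchy_depth > 0
                and parents
                and rng.random() < 0.4
            )
            if nestable:
                parent = parents[int(rng.integers(len(parents)))]
                parent_members = members_of[parent]
                child_size = max(config.pathway_size_min, len(parent_members) // 2)
                if child_size < len(parent_members):
                    members = list(
                        rng.choice(parent_members, size=child_size, replace=False)
                    )
                    manifest_rows.append(("pathway_nesting", f"{tag}:{pw_id}",
                                          f"{tag}:{parent}"))
                else:
                    nestable = False
            if not nestable:
                size = int(rng.integers(config.pathway_size_min,
                                        config.pathway_size_max + 1))
                members = list(rng.choice(pool, size=size, replace=False))
            members_of[pw_id] = members
            pathway_rows.append((pw_id, f"{tag} pathway {p_idx:04d}"))
            for native in members:
                membership_rows.append((pw_id, native))
            # only reasonably large pathways parent further nesting levels
            if len(members) >= 2 * config.pathway_size_min:
                parents.append(pw_id)
            p_idx += 1

        # promiscuous analytes: planted into every pathway of this source
        promiscuous = met_ids[: config.promiscuous_analyte_count]
        for native in promiscuous:
            for pw_id in members_of:
                if native not in members_of[pw_id]:
                    members_of[pw_id].append(native)
                    membership_rows.append((pw_id, native))
            manifest_rows.append(
                ("promiscuous_analyte", f"{tag}:{native}", str(len(members_of)))
            )

        n_cat = max(1, config.n_genes // 4)
        cat_genes = rng.choice(gene_ids, size=n_cat, replace=False)
        cat_mets = rng.choice(met_ids, size=n_cat, replace=False)
        catalysis_rows = sorted(set(zip(cat_genes, cat_mets)))

        terms = [("biofluid", "blood"), ("biofluid", "urine"),
                 ("cellular_location", "mitochondria"), ("origin", "food"),
                 ("tissue", "liver")]
        ontology_rows = []
        n_onto = max(1, config.n_metabolites // 5)
        chosen = rng.choice(met_ids, size=n_onto, replace=False)
        for i, native in enumerate(chosen):
            category, term = terms[i % len(terms)]
            ontology_rows.append((native, category, term))

        dumps.append(
            SourceDump(
                source=tag,
                analytes=pd.DataFrame(
                    analyte_rows, columns=DUMP_TABLES["analytes"][1]),
                id_links=pd.DataFrame(link_rows, columns=DUMP_TABLES["id_links"][1]),
                synonyms=pd.DataFrame(
                    sorted(set(synonym_rows)), columns=DUMP_TABLES["synonyms"][1]),
                pathways=pd.DataFrame(pathway_rows, columns=DUMP_TABLES["pathways"][1]),
                memberships=pd.DataFrame(
                    sorted(set(membership_rows)), columns=DUMP_TABLES["memberships"][1]),
                catalysis=pd.DataFrame(
                    catalysis_rows, columns=DUMP_TABLES["catalysis"][1]),
                ontology=pd.DataFrame(
                    sorted(set(ontology_rows)), columns=DUMP_TABLES["ontology"][1]),
            )
        )
    manifest = pd.DataFrame(manifest_rows, columns=["truth_type", "key", "value"])
    return dumps, manifest


def true_partition(manifest: pd.DataFrame) -> Dict[str, Set[str]]:
    """Ground-truth co-reference groups: true key -> {"source:native_id", ...}."""
    part: Dict[str, Set[str]] = {}
    sub = manifest[manifest["truth_type"] == "analyte_partition"]
    for row in sub.itertuples(index=False):
        part.setdefault(row.value, set()).add(row.key)
    return part


def planted_enrichment_dump(
    seed: int,
    n_background_metabolites: int = 1000,
    target_size: int = 30,
    n_decoys: int = 50,
    decoy_size_range: Tuple[int, int] = (10, 100),
    source: str = "kegg",
) -> Tuple[SourceDump, str]:
    """Single-source dump with one target pathway and random decoy pathways.

    The metabolite universe has ``n_background_metabolites`` members; the
    target pathway takes the first ``target_size`` of them and each decoy is
    a uniform random draw.  Returns the dump and the target pathway's native
    ID.
    """
    if target_size > n_background_metabolites:
        raise ConfigError("target pathway larger than the metabolite universe")
    rng = np.random.default_rng(seed)
    mets = [f"{source.upper()}_M{i:05d}" for i in range(n_background_metabolites)]
    analyte_rows = [(m, "metabolite", f"met_{i:05d}") for i, m in enumerate(mets)]
    target_id = f"{source.upper()}_PW_TARGET"
    pathway_rows = [(target_id, "planted target pathway")]
    membership_rows = [(target_id, m) for m in mets[:target_size]]
    lo, hi = decoy_size_range
    hi = min(hi, n_background_metabolites)
    lo = min(lo, hi)
    for d in range(n_decoys):
        pw_id = f"{source.upper()}_PW_DECOY{d:03d}"
        size = int(rng.integers(lo, hi + 1))
        pathway_rows.append((pw_id, f"decoy pathway {d:03d}"))
        for m in rng.choice(mets, size=size, replace=False):
            membership_rows.append((pw_id, m))
    dump = SourceDump(
        source=source,
        analytes=pd.DataFrame(analyte_rows, columns=DUMP_TABLES["analytes"][1]),
        id_links=pd.DataFrame(columns=DUMP_TABLES["id_links"][1]),
        synonyms=pd.DataFrame(columns=DUMP_TABLES["synonyms"][1]),
        pathways=pd.DataFrame(pathway_rows, columns=DUMP_TABLES["pathways"][1]),
        memberships=pd.DataFrame(
            sorted(set(membership_rows)), columns=DUMP_TABLES["memberships"][1]),
    )
    return dump, target_id


def plant_enriched_list(
    dump: SourceDump,
    target_pathway: str,
    n_from_pathway: int,
    n_background: int,
    seed: int,
) -> Tuple[List[str], Dict[str, object]]:
    """Mix target-pathway members with uniform off-target analytes.

    Returns the analyte list (native IDs) and a truth record naming the
    target and which entries came from it.
    """
    members = dump.memberships.loc[
        dump.memberships["pathway_id"] == target_pathway, "native_id"
    ].tolist()
    if not members:
        raise InputError(f"target pathway {target_pathway!r} not found or empty")
    if n_from_pathway > len(members):
        raise ConfigError(
            f"requested {n_from_pathway} members but pathway has {len(members)}"
        )
    outside = sorted(set(dump.analytes["native_id"]) - set(members))
    if n_background > len(outside):
        raise ConfigError(
            f"requested {n_background} background analytes but only "
            f"{len(outside)} are outside the target"
        )
    rng = np.random.default_rng(seed)
    from_target = sorted(rng.choice(members, size=n_from_pathway, replace=False)) \
        if n_from_pathway else []
    background = sorted(rng.choice(outside, size=n_background, replace=False)) \
        if n_background else []
    truth = {
        "target_pathway": target_pathway,
        "from_target": list(from_target),
        "background": list(background),
    }
    return list(from_target) + list(background), truth
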