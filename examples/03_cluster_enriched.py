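"""Cluster redundant enriched pathways by analyte overlap.

Constructs two disjoint families of heavily overlapping pathways (mimicking
nested hierarchies and cross-source duplicates), enriches both, and shows
the fuzzy multiple-linkage clustering collapsing each family to one cluster.
"""
import numpy as np

from crosspath import (
    BackgroundSpec,
    ClusterParams,
    cluster_enrichment_results,
    ingest,
    run_enrichment,
)
from crosspath.ingest import SourceDump, DUMP_TABLES
import pandas as pd

rng = np.random.default_rng(5)
analytes, pathways, memberships = [], [], []
for fam in ("a", "b"):
    pool = [f"{fam.upper()}{i}" for i in range(18)]
    analytes += [(m, "metabolite", m.lower()) for m in pool]
    for k in range(6):
        pid = f"PW_{fam}{k}"
        pathways.append((pid, f"family {fam} pathway {k}"))
        members = pool[:12] + list(rng.choice(pool[12:], size=3, replace=False))
        memberships += [(pid, m) for m in set(members)]

dump = SourceDump(
    source="kegg",
    analytes=pd.DataFrame(analytes, columns=DUMP_TABLES["analytes"][1]),
    id_links=pd.DataFrame(columns=DUMP_TABLES["id_links"][1]),
    synonyms=pd.DataFrame(columns=DUMP_TABLES["synonyms"][1]),
    pathways=pd.DataFrame(pathways, columns=DUMP_TABLES["pathways"][1]),
    memberships=pd.DataFrame(memberships, columns=DUMP_TABLES["memberships"][1]),
)
store, _ = ingest([dump])
result = run_enrichment(
    [f"a{i}" for i in range(12)] + [f"b{i}" for i in range(12)], store,
    backgrounds=BackgroundSpec(metabolite={"kegg": 36}), sources=["kegg"])

annotated, clusters, merge_log = cluster_enrichment_results(
    result.table, store, ClusterParams())
print(annotated[["pathway_name", "p_comb", "cluster_labels"]].to_string(index=False))
print(f"\n{len(clusters)} final clusters after {len(merge_log)} merges")
# Every pathway within a family shares >= 12 of ~15 members, so each family
# seeds many near-identical clusters that the merge loop collapses to one;
# the two families share no analytes, so they never merge with each other.
for absorbed, survivor, score in merge_log[:3]:
    print(f"  merge: {absorbed} -> {survivor} at overlap {score:.2f}")
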