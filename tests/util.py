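"""Shared randomized-fixture builders and independent oracles for tests."""
from math import comb
from typing import Dict, List, Set, Tuple

import networkx as nx
import numpy as np

from crosspath.ids import SourceIdentifier
from crosspath.ingest import SourceDump

from conftest import make_dump


def random_link_fixture(rng: np.random.Generator,
                        max_nodes: int = 100) -> Tuple[List[SourceDump], Dict]:
    """Random multi-source identifier-association fixture.

    Analytes are spread over 1-4 dumps in random order; cross-links are
    realized through shared reference identifiers, so the true co-reference
    partition is the connected-component partition of the pooled link graph.
    Returns the dumps plus the oracle partition over "source:native" keys,
    computed independently with networkx connected components.
    """
    n = int(rng.integers(5, max_nodes + 1))
    k = int(rng.integers(1, 5))
    tags = ["kegg", "reactome", "wiki", "hmdb"][:k]
    assignment = rng.integers(0, k, size=n)
    atype = ["metabolite" if rng.random() < 0.7 else "gene" for _ in range(n)]
    n_edges = int(rng.integers(0, 2 * n))
    edges = set()
    for _ in range(n_edges):
        u, v = rng.integers(0, n, size=2)
        if u != v and atype[u] == atype[v]:  # kinds never mix under one ID
            edges.add((min(u, v), max(u, v)))

    links_per_node: Dict[int, Set[Tuple[str, str]]] = {i: set() for i in range(n)}
    for e_idx, (u, v) in enumerate(sorted(edges)):
        ref_source = "chebi" if atype[u] == "metabolite" else "uniprot"
        ref = (ref_source, f"REF{e_idx:05d}")
        links_per_node[u].add(ref)
        links_per_node[v].add(ref)

    dumps = []
    for t_idx, tag in enumerate(tags):
        rows = [
            (f"N{i:05d}", atype[i], f"analyte_{i}")
            for i in range(n) if assignment[i] == t_idx
        ]
        links = [
            (f"N{i:05d}", src, ref)
            for i in range(n) if assignment[i] == t_idx
            for src, ref in sorted(links_per_node[i])
        ]
        dumps.append(make_dump(tag, analytes=rows, links=links))
    order = rng.permutation(len(dumps))
    dumps = [dumps[i] for i in order]

    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    graph.add_edges_from(edges)
    oracle = {}
    for c_idx, component in enumerate(nx.connected_components(graph)):
        for i in component:
            oracle[f"{tags[assignment[i]]}:N{i:05d}"] = c_idx
    return dumps, oracle


def partition_from_mapping(dumps, mapping) -> Dict[str, int]:
    """Observed partition: each dump-native analyte key -> its unified ID."""
    out = {}
    for dump in dumps:
        for native in dump.analytes["native_id"]:
            rid = mapping.lookup(SourceIdentifier(dump.source, native))
            out[f"{dump.source}:{native}"] = rid
    return out


def same_partition(a: Dict[str, object], b: Dict[str, object]) -> bool:
    """True when two labelings induce identical groupings of the same keys."""
    if set(a) != set(b):
        return False
    groups_a: Dict[object, Set[str]] = {}
    groups_b: Dict[object, Set[str]] = {}
    for key in a:
        groups_a.setdefault(a[key], set()).add(key)
        groups_b.setdefault(b[key], set()).add(key)
    return set(map(frozenset, groups_a.values())) == set(map(frozenset, groups_b.values()))


def exact_hypergeom_tail(hits: int, list_size: int, pathway_size: int,
                         background: int) -> float:
    """Exhaustive upper-tail summation with exact integer arithmetic."""
    total = comb(background, list_size)
    acc = 0
    for x in range(hits, min(list_size, pathway_size) + 1):
        acc += comb(pathway_size, x) * comb(background - pathway_size, list_size - x)
    return acc / total


def textbook_bh(pvals: List[float]) -> List[float]:
    """Step-up Benjamini-Hochberg, coded directly from the definition."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adjusted = [0.0] * n
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, pvals[i] * n / rank)
        adjusted[i] = running_min
    return adjusted


def textbook_holm(pvals: List[float]) -> List[float]:
    """Step-down Holm, coded directly from the definition."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adjusted = [0.0] * n
    running_max = 0.0
    for rank, i in enumerate(order, start=1):
        running_max = max(running_max, min(1.0, (n - rank + 1) * pvals[i]))
        adjusted[i] = running_max
    return adjusted
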