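import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from crosspath.ingest import DUMP_TABLES, SourceDump, ingest

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


def make_dump(source, analytes, links=(), synonyms=(), pathways=(),
              memberships=(), catalysis=(), ontology=()):
    """Build a SourceDump from row tuples (headers per the dump format)."""
    return SourceDump(
        source=source,
        analytes=pd.DataFrame(analytes, columns=DUMP_TABLES["analytes"][1]),
        id_links=pd.DataFrame(list(links), columns=DUMP_TABLES["id_links"][1]),
        synonyms=pd.DataFrame(list(synonyms), columns=DUMP_TABLES["synonyms"][1]),
        pathways=pd.DataFrame(list(pathways), columns=DUMP_TABLES["pathways"][1]),
        memberships=pd.DataFrame(list(memberships), columns=DUMP_TABLES["memberships"][1]),
        catalysis=pd.DataFrame(list(catalysis), columns=DUMP_TABLES["catalysis"][1]),
        ontology=pd.DataFrame(list(ontology), columns=DUMP_TABLES["ontology"][1]),
    )


@pytest.fixture
def dump_factory():
    return make_dump


@pytest.fixture
def toy_dumps():
    """Two small dumps sharing glucose through a chebi cross-link."""
    kegg = make_dump(
        "kegg",
        analytes=[
            ("K_M1", "metabolite", "glucose"),
            ("K_M2", "metabolite", "pyruvate"),
            ("K_M3", "metabolite", "orphan metabolite"),
            ("K_G1", "gene", "HK1"),
        ],
        links=[
            ("K_M1", "chebi", "4167"),
            ("K_M1", "pubchem", "3333"),
            ("K_M1", "hmdb", "HMDB0000122"),
        ],
        synonyms=[("K_M1", "dextrose"), ("K_M2", "pyr")],
        pathways=[("KPW1", "Glycolysis")],
        memberships=[("KPW1", "K_M1"), ("KPW1", "K_M2"), ("KPW1", "K_G1")],
        catalysis=[("K_G1", "K_M1"), ("K_G1", "K_M2")],
        ontology=[("K_M1", "biofluid", "blood"), ("K_M2", "biofluid", "blood")],
    )
    wiki = make_dump(
        "wiki",
        analytes=[
            ("W_M1", "metabolite", "glucose"),
            ("W_M4", "metabolite", "lactate"),
        ],
        links=[("W_M1", "chebi", "4167")],
        synonyms=[("W_M4", "milk acid")],
        pathways=[("WPW1", "Glycolysis")],
        memberships=[("WPW1", "W_M1"), ("WPW1", "W_M4")],
    )
    return [kegg, wiki]


@pytest.fixture
def toy_store(toy_dumps):
    store, _ = ingest(toy_dumps)
    return store
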