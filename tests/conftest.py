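import logging

import pytest

from traitlink.ontology import OntologyGraph, OntologyTerm

logging.getLogger("traitlink").setLevel(logging.ERROR)


def make_graph(edges: dict[str, list[str]], namespace: str = "BP",
               obsolete: set[str] | None = None) -> OntologyGraph:
    """Build a graph from {term: [parents]}; terms with no parents are roots."""
    obsolete = obsolete or set()
    return OntologyGraph(
        OntologyTerm(
            term_id=term,
            name=term,
            namespace=namespace,
            parent_ids=frozenset(parents),
            obsolete=term in obsolete,
        )
        for term, parents in edges.items()
    )


@pytest.fixture
def chain_graph() -> OntologyGraph:
    """root <- a <- b <- c, a single namespace chain."""
    return make_graph({"root": [], "a": ["root"], "b": ["a"], "c": ["b"]})


@pytest.fixture
def diamond_graph() -> OntologyGraph:
    """d has two parents b and c, both children of root a."""
    return make_graph({"a": [], "b": ["a"], "c": ["a"], "d": ["b", "c"]})
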