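"""Ontology parsing, annotation propagation, information content and term similarity.

The ontology is a rooted DAG per namespace (``BP``, ``MF``, ``CC``); annotations
are propagated to ancestors (true-path rule) before information content (IC) is
computed, and term-term similarity defaults to the Lin measure
``2 * IC(MICA) / (IC(t1) + IC(t2))`` where the MICA is the common ancestor
(including the terms themselves) with maximal IC.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Callable, Iterable, Mapping
from dataclasses import dataclass, field

import networkx as nx

logger = logging.getLogger(__name__)

NAMESPACES = ("BP", "MF", "CC")

_OBO_NAMESPACE = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
    "BP": "BP",
    "MF": "MF",
    "CC": "CC",
}

_GAF_ASPECT = {"P": "BP", "F": "MF", "C": "CC"}

#: Signature of a pluggable term-term similarity source. Implementations must be
#: symmetric and return values in [0, 1]. ``lin`` is the default; alternative
#: measures (e.g. an integrated/adjusted similarity) can be registered under a
#: new name without touching the set-level aggregation code.
TermSimilarity = Callable[[str, str], float]

TERM_SIMILARITY_REGISTRY: dict[str, Callable[..., TermSimilarity]] = {}


class OntologyError(ValueError):
    """Raised for structural problems in the ontology or its annotations."""


@dataclass(frozen=True)
class OntologyTerm:
    term_id: str
    name: str
    namespace: str
    parent_ids: frozenset[str] = frozenset()
    obsolete: bool = False


class OntologyGraph:
    """A validated DAG of ontology terms with one root per namespace.

    Parent edges combine ``is_a`` and (optionally) ``part_of``. Construction
    verifies acyclicity, namespace-pure edges, and that obsolete terms have no
    children; ``ancestors`` memoises the reflexive transitive closure.
    """

    def __init__(self, terms: Iterable[OntologyTerm]):
        self.terms: dict[str, OntologyTerm] = {}
        for term in terms:
            if term.term_id in self.terms:
                raise OntologyError(f"duplicate term id {term.term_id!r}")
            self.terms[term.term_id] = term
        self._validate()
        self.roots: dict[str, str] = self._find_roots()
        self._ancestors_cache: dict[str, frozenset[str]] = {}

    def _validate(self) -> None:
        graph = nx.DiGraph()
        for term in self.terms.values():
            graph.add_node(term.term_id)
            for parent_id in term.parent_ids:
                parent = self.terms.get(parent_id)
                if parent is None:
                    raise OntologyError(
                        f"{term.term_id} references unknown parent {parent_id!r}"
                    )
                if parent.namespace != term.namespace:
                    raise OntologyError(
                        f"cross-namespace edge {term.term_id} ({term.namespace}) "
                        f"-> {parent_id} ({parent.namespace})"
                    )
                if parent.obsolete:
                    raise OntologyError(
                        f"obsolete term {parent_id} has child {term.term_id}"
                    )
                graph.add_edge(term.term_id, parent_id)
        try:
            cycle = nx.find_cycle(graph)
        except nx.NetworkXNoCycle:
            return
        path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
        raise OntologyError(f"ontology contains a cycle: {path}")

    def _find_roots(self) -> dict[str, str]:
        roots: dict[str, str] = {}
        for term in self.terms.values():
            if term.obsolete or term.parent_ids:
                continue
            if term.namespace in roots:
                raise OntologyError(
                    f"multiple roots in namespace {term.namespace}: "
                    f"{roots[term.namespace]} and {term.term_id}"
                )
            roots[term.namespace] = term.term_id
        return roots

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def namespace_of(self, term_id: str) -> str:
        return self.terms[term_id].namespace

    def terms_in_namespace(self, namespace: str) -> list[str]:
        return sorted(
            t.term_id
            for t in self.terms.values()
            if t.namespace == namespace and not t.obsolete
        )

    def ancestors(self, term_id: str) -> frozenset[str]:
        """Reflexive transitive closure over parent edges (includes ``term_id``)."""
        cached = self._ancestors_cache.get(term_id)
        if cached is not None:
            return cached
        term = self.terms.get(term_id)
        if term is None:
            raise KeyError(f"unknown term {term_id!r}")
        if term.obsolete:
            raise OntologyError(f"ancestors of obsolete term {term_id}")
        # Iterative post-order so deep chains do not hit the recursion limit.
        stack = [term_id]
        while stack:
            current = stack[-1]
            if current in self._ancestors_cache:
                stack.pop()
                continue
            pending = [
                p for p in self.terms[current].parent_ids
                if p not in self._ancestors_cache
            ]
            if pending:
                stack.extend(pending)
                continue
            closure: set[str] = {current}
            for parent_id in self.terms[current].parent_ids:
                closure |= self._ancestors_cache[parent_id]
            self._ancestors_cache[current] = frozenset(closure)
            stack.pop()
        return self._ancestors_cache[term_id]


def parse_obo(path: str, *, part_of: bool = True) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 file into an :class:`OntologyGraph`.

    ``is_a`` lines always become parent edges; ``relationship: part_of`` lines
    do too unless ``part_of=False``. Obsolete stanzas are retained but flagged.
    """
    terms: list[OntologyTerm] = []
    stanza: dict[str, list[str]] | None = None

    def flush() -> None:
        if stanza is None:
            return
        term_id = stanza.get("id", [None])[0]
        if term_id is None:
            raise OntologyError("[Term] stanza without an id")
        raw_ns = stanza.get("namespace", [None])[0]
        if raw_ns is None:
            raise OntologyError(f"term {term_id} has no namespace tag")
        namespace = _OBO_NAMESPACE.get(raw_ns)
        if namespace is None:
            raise OntologyError(f"term {term_id}: unknown namespace {raw_ns!r}")
        obsolete = stanza.get("is_obsolete", ["false"])[0].lower() == "true"
        parents: set[str] = set()
        for value in stanza.get("is_a", []):
            parents.add(value.split("!")[0].strip())
        if part_of:
            for value in stanza.get("relationship", []):
                fields = value.split("!")[0].split()
                if len(fields) >= 2 and fields[0] == "part_of":
                    parents.add(fields[1])
        terms.append(
            OntologyTerm(
                term_id=term_id,
                name=stanza.get("name", [""])[0],
                namespace=namespace,
                parent_ids=frozenset(parents),
                obsolete=obsolete,
            )
        )

    with open(path, encoding="utf-8") as handle:
        in_term = False
        for raw in handle:
            line = raw.strip()
            if line.startswith("["):
                if in_term:
                    flush()
                    stanza = None
                in_term = line == "[Term]"
                if in_term:
                    stanza = {}
                continue
            if not in_term or not line or line.startswith("!"):
                continue
            key, _, value = line.partition(":")
            assert stanza is not None
            stanza.setdefault(key.strip(), []).append(value.strip())
        if in_term:
            flush()
    return OntologyGraph(terms)


@dataclass
class AnnotationCorpus:
    """Gene-term annotations for one namespace, direct and ancestry-closed.

    ``term_gene_count`` and ``ic`` are computed from the propagated sets;
    ``ic(t) = -ln(term_gene_count(t) / n_annotated_genes)`` in nats.
    """

    namespace: str
    direct: dict[str, frozenset[str]]
    propagated: dict[str, frozenset[str]]
    term_gene_count: dict[str, int]
    n_annotated_genes: int
    ic: dict[str, float]
    _gene_index: dict[str, int] | None = field(default=None, repr=False)

    def genes_with_term(self, term_id: str) -> int:
        return self.term_gene_count.get(term_id, 0)


def propagate_annotations(
    graph: OntologyGraph,
    direct: Mapping[str, Iterable[str]],
    *,
    namespace: str | None = None,
) -> AnnotationCorpus:
    """Close direct annotations under ancestry and compute counts and IC.

    All annotated terms must exist in ``graph`` and share one namespace
    (``namespace`` filters a mixed input down to one). Annotations to obsolete
    terms are dropped with a warning; genes left without terms are excluded.
    """
    clean_direct: dict[str, frozenset[str]] = {}
    propagated: dict[str, frozenset[str]] = {}
    seen_namespace: str | None = namespace
    for gene_id in sorted(direct):
        kept: set[str] = set()
        closure: set[str] = set()
        for term_id in direct[gene_id]:
            term = graph.terms.get(term_id)
            if term is None:
                raise OntologyError(
                    f"gene {gene_id} annotated to unknown term {term_id!r}"
                )
            if term.obsolete:
                logger.warning(
                    "dropping annotation of %s to obsolete term %s", gene_id, term_id
                )
                continue
            if namespace is not None and term.namespace != namespace:
                continue
            if seen_namespace is None:
                seen_namespace = term.namespace
            elif term.namespace != seen_namespace:
                raise OntologyError(
                    f"mixed namespaces in annotation input ({seen_namespace} vs "
                    f"{term.namespace}); propagate one namespace per call"
                )
            kept.add(term_id)
            closure |= graph.ancestors(term_id)
        if kept:
            clean_direct[gene_id] = frozenset(kept)
            propagated[gene_id] = frozenset(closure)

    term_gene_count: dict[str, int] = {}
    for terms in propagated.values():
        for term_id in terms:
            term_gene_count[term_id] = term_gene_count.get(term_id, 0) + 1
    n_annotated = len(propagated)
    ic = {
        term_id: -math.log(count / n_annotated)
        for term_id, count in term_gene_count.items()
    }
    return AnnotationCorpus(
        namespace=seen_namespace if seen_namespace is not None else "BP",
        direct=clean_direct,
        propagated=propagated,
        term_gene_count=term_gene_count,
        n_annotated_genes=n_annotated,
        ic=ic,
    )


def lin_similarity(
    corpus: AnnotationCorpus, graph: OntologyGraph, t1: str, t2: str
) -> float:
    """Lin similarity between two terms of one namespace, in [0, 1].

    Terms with no annotated genes have undefined IC and are rejected. The
    degenerate pair with ``IC(t1) + IC(t2) == 0`` returns 0 by convention.
    """
    ns1, ns2 = graph.namespace_of(t1), graph.namespace_of(t2)
    if ns1 != ns2:
        raise OntologyError(f"cross-namespace pair {t1} ({ns1}) vs {t2} ({ns2})")
    ic1 = corpus.ic.get(t1)
    ic2 = corpus.ic.get(t2)
    if ic1 is None or ic2 is None:
        missing = t1 if ic1 is None else t2
        raise OntologyError(f"term {missing} has no annotated genes; IC undefined")
    denom = ic1 + ic2
    if denom == 0.0:
        return 0.0
    common = graph.ancestors(t1) & graph.ancestors(t2)
    mica_ic = max((corpus.ic[t] for t in common if t in corpus.ic), default=0.0)
    return min(1.0, 2.0 * mica_ic / denom)


class LinTermSimilarity:
    """Cached Lin similarity over a fixed corpus; usable as a `TermSimilarity`."""

    def __init__(self, corpus: AnnotationCorpus, graph: OntologyGraph):
        self.corpus = corpus
        self.graph = graph
        self._cache: dict[tuple[str, str], float] = {}

    def __call__(self, t1: str, t2: str) -> float:
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        value = self._cache.get(key)
        if value is None:
            value = lin_similarity(self.corpus, self.graph, key[0], key[1])
            self._cache[key] = value
        return value


TERM_SIMILARITY_REGISTRY["lin"] = LinTermSimilarity


def make_term_similarity(
    name: str, corpus: AnnotationCorpus, graph: OntologyGraph
) -> TermSimilarity:
    try:
        factory = TERM_SIMILARITY_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown term similarity {name!r}; "
            f"registered: {sorted(TERM_SIMILARITY_REGISTRY)}"
        ) from None
    return factory(corpus, graph)


def read_annotation_tsv(path: str) -> dict[str, set[str]]:
    """Read a two-column gene_id<TAB>term_id table (optional header, # comments)."""
    direct: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            gene_id, term_id = fields[0], fields[1]
            if lineno == 1 and term_id.lower() in {"term_id", "go_id"}:
                continue
            direct.setdefault(gene_id, set()).add(term_id)
    return direct


def read_gaf(path: str, namespace: str | None = None) -> dict[str, set[str]]:
    """Read GAF 2.x annotations (columns 2, 4, 5, 9: gene, qualifier, term, aspect).

    Rows with a NOT qualifier are skipped; ``namespace`` restricts to one aspect.
    """
    direct: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as handle:
        for raw in handle:
            if raw.startswith("!") or not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            gene_id, qualifier, term_id, aspect = (
                fields[1],
                fields[3],
                fields[4],
                fields[8],
            )
            if "NOT" in qualifier.split("|"):
                continue
            ns = _GAF_ASPECT.get(aspect)
            if namespace is not None and ns != namespace:
                continue
            direct.setdefault(gene_id, set()).add(term_id)
    return direct
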