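"""Shared pipeline engine: region-to-gene mapping, filtering, enrichment and
similarity, in one code path used both for observed data and for permutation
replicates."""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

from traitlink.enrichment import AnnotationMatrix, TraitTermLink, link_traits_to_terms
from traitlink.genome_qtl import (
    GeneLocus,
    GenomeIndex,
    PipelineConfig,
    Trait,
    apply_filters,
    assign_genes,
)
from traitlink.ontology import (
    AnnotationCorpus,
    OntologyGraph,
    TermSimilarity,
    make_term_similarity,
)
from traitlink.trait_similarity import TraitSimilarityMatrix, similarity_matrix


@dataclass
class PipelineResources:
    """Immutable inputs reused across pipeline invocations (observed + permuted)."""

    genome: GenomeIndex
    graphs: dict[str, OntologyGraph]
    corpora: dict[str, AnnotationCorpus]
    config: PipelineConfig
    matrices: dict[str, AnnotationMatrix] = field(default_factory=dict)
    termsims: dict[str, TermSimilarity] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for namespace, corpus in self.corpora.items():
            self.matrices.setdefault(namespace, AnnotationMatrix(corpus))
            self.termsims.setdefault(
                namespace,
                make_term_similarity(
                    self.config.term_similarity, corpus, self.graphs[namespace]
                ),
            )

    @property
    def namespaces(self) -> list[str]:
        return sorted(self.corpora)

    @property
    def n_total_genes(self) -> int:
        return len(self.genome)

    @classmethod
    def build(
        cls,
        genes: Sequence[GeneLocus],
        graphs: Mapping[str, OntologyGraph],
        corpora: Mapping[str, AnnotationCorpus],
        config: PipelineConfig,
    ) -> "PipelineResources":
        return cls(
            genome=GenomeIndex(genes),
            graphs=dict(graphs),
            corpora=dict(corpora),
            config=config,
        )


@dataclass
class PipelineOutputs:
    traits: list[Trait]
    exclusion_log: object
    links: dict[str, list[TraitTermLink]]
    matrices: dict[str, TraitSimilarityMatrix | None]

    @property
    def all_links(self) -> list[TraitTermLink]:
        out: list[TraitTermLink] = []
        for namespace in sorted(self.links):
            out.extend(self.links[namespace])
        return out


def run_similarity_pipeline(
    dataset: Sequence[Trait],
    resources: PipelineResources,
    *,
    with_similarity: bool = True,
) -> PipelineOutputs:
    """Map regions to genes, filter, enrich per namespace, build similarity.

    ``dataset`` carries regions (gene sets need not be assigned); this is the
    single entry point shared by the observed analysis and the random-region
    permutation scheme.
    """
    config = resources.config
    assigned = assign_genes(dataset, resources.genome)
    filtered, exclusion_log = apply_filters(assigned, config)
    links: dict[str, list[TraitTermLink]] = {}
    matrices: dict[str, TraitSimilarityMatrix | None] = {}
    for namespace in resources.namespaces:
        ns_links = link_traits_to_terms(
            filtered,
            resources.corpora[namespace],
            resources.graphs[namespace],
            config,
            n_total_genes=resources.n_total_genes,
            matrix=resources.matrices[namespace],
        )
        links[namespace] = ns_links
        if not with_similarity:
            matrices[namespace] = None
            continue
        n_linked = len({l.trait_id for l in ns_links})
        if n_linked < 2:
            matrices[namespace] = None
        else:
            matrices[namespace] = similarity_matrix(
                ns_links,
                resources.corpora[namespace],
                resources.graphs[namespace],
                namespace,
                termsim=resources.termsims[namespace],
                symmetric=config.symmetric_bma,
            )
    return PipelineOutputs(
        traits=filtered,
        exclusion_log=exclusion_log,
        links=links,
        matrices=matrices,
    )


def pair_counts(
    matrix: TraitSimilarityMatrix | None, thresholds: Sequence[float]
) -> dict[float, int]:
    """Number of unordered off-diagonal trait pairs with similarity >= threshold."""
    counts = {float(t): 0 for t in thresholds}
    if matrix is None:
        return counts
    n = len(matrix.trait_ids)
    for threshold in counts:
        total = 0
        for i in range(n):
            for j in range(i + 1, n):
                if matrix.values[i, j] >= threshold - 1e-12:
                    total += 1
        counts[threshold] = total
    return counts
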