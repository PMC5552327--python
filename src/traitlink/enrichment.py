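"""Trait-to-term overrepresentation: Fisher tests, BH correction, occurrence
and generality gates.

A trait is linked to a term when all three gates hold: the one-sided Fisher
(hypergeometric upper tail) p-value survives BH at the configured FDR within
the trait's candidate set, the term occurs in at least the configured fraction
of the trait's regions (via propagated annotations), and the term annotates at
most the configured fraction of all genes in the genome.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from traitlink.genome_qtl import PipelineConfig, Trait
from traitlink.ontology import AnnotationCorpus, OntologyGraph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TraitTermLink:
    trait_id: str
    term_id: str
    namespace: str
    p_raw: float
    p_adj: float
    k_trait: int
    K_genome: int
    n_trait: int
    N_genome: int
    occ_regions: int
    n_regions: int
    trait_type: str = ""


def fisher_pvalue(k_trait: int, K_genome: int, n_trait: int, N_genome: int) -> float:
    """One-sided overrepresentation p-value: P(X >= k) for X ~ Hypergeom(N, K, n)."""
    if not (0 <= k_trait <= min(K_genome, n_trait)
            and K_genome <= N_genome and n_trait <= N_genome):
        raise ValueError(
            f"invalid hypergeometric bounds k={k_trait}, K={K_genome}, "
            f"n={n_trait}, N={N_genome}"
        )
    if k_trait == 0:
        return 1.0
    return float(hypergeom.sf(k_trait - 1, N_genome, K_genome, n_trait))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def occurrence_count(trait: Trait, term_id: str, corpus: AnnotationCorpus) -> int:
    """Regions of the trait containing >= 1 gene whose propagated set has the term."""
    count = 0
    for region in trait.regions:
        for gene_id in region.gene_ids:
            if term_id in corpus.propagated.get(gene_id, frozenset()):
                count += 1
                break
    return count


def occurrence_threshold(n_regions: int, occurrence_fraction: float) -> int:
    """Smallest count c with c / n_regions >= occurrence_fraction."""
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    return math.ceil(occurrence_fraction * n_regions - 1e-12)


def generality_filter(
    corpus: AnnotationCorpus,
    term_id: str,
    generality_max_fraction: float,
    n_total_genes: int | None = None,
) -> bool:
    """Keep a term iff it annotates <= the given fraction of all genes.

    ``n_total_genes`` is the genome-wide gene count; by default the number of
    annotated genes in the corpus is used.
    """
    total = n_total_genes if n_total_genes is not None else corpus.n_annotated_genes
    return corpus.genes_with_term(term_id) / total <= generality_max_fraction


class AnnotationMatrix:
    """Dense gene x term boolean view of a propagated corpus.

    Built once per corpus and reused across permutation replicates so that the
    enrichment stage reduces to vectorized column sums.
    """

    def __init__(self, corpus: AnnotationCorpus):
        self.corpus = corpus
        self.gene_ids = sorted(corpus.propagated)
        self.term_ids = sorted(corpus.term_gene_count)
        self.gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self.term_index = {t: j for j, t in enumerate(self.term_ids)}
        self.matrix = np.zeros((len(self.gene_ids), len(self.term_ids)), dtype=bool)
        for gene_id, terms in corpus.propagated.items():
            row = self.gene_index[gene_id]
            for term_id in terms:
                self.matrix[row, self.term_index[term_id]] = True
        self.term_counts = self.matrix.sum(axis=0)

    def gene_rows(self, gene_ids) -> np.ndarray:
        return np.fromiter(
            (self.gene_index[g] for g in gene_ids if g in self.gene_index),
            dtype=np.int64,
        )


def link_traits_to_terms(
    dataset: Sequence[Trait],
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    config: PipelineConfig,
    *,
    n_total_genes: int | None = None,
    matrix: AnnotationMatrix | None = None,
) -> list[TraitTermLink]:
    """Compute all trait-term links for one namespace.

    Candidate terms per trait are the propagated terms of its genes that pass
    the generality filter; Fisher p-values use the whole annotated genome as
    background; BH is applied within each trait's candidate set (or globally
    with ``config.global_bh``); retained links must also meet the occurrence
    threshold. Output is sorted by (trait_id, p_adj, term_id).
    """
    if matrix is None:
        matrix = AnnotationMatrix(corpus)
    total = n_total_genes if n_total_genes is not None else corpus.n_annotated_genes
    max_count = config.generality_max_fraction * total
    general_ok = matrix.term_counts <= max_count
    N_genome = corpus.n_annotated_genes

    per_trait: list[tuple[Trait, np.ndarray, np.ndarray, np.ndarray,
                          np.ndarray, np.ndarray, int, int]] = []
    for trait in dataset:
        trait_rows = matrix.gene_rows(trait.gene_ids)
        if trait_rows.size == 0:
            logger.warning(
                "trait %s has no annotated genes in namespace %s; no links",
                trait.trait_id, corpus.namespace,
            )
            continue
        k = matrix.matrix[trait_rows].sum(axis=0)
        candidate = (k > 0) & general_ok
        if not candidate.any():
            continue
        cand_idx = np.flatnonzero(candidate)
        n_trait = int(trait_rows.size)
        K = matrix.term_counts[cand_idx]
        # occurrence: a region counts when any of its genes carries the term
        occ = np.zeros(cand_idx.size, dtype=np.int64)
        for region in trait.regions:
            rows = matrix.gene_rows(region.gene_ids)
            if rows.size:
                occ += matrix.matrix[np.ix_(rows, cand_idx)].any(axis=0)
        threshold = occurrence_threshold(trait.n_regions, config.occurrence_fraction)
        per_trait.append(
            (trait, cand_idx, k[cand_idx], K, None, occ, threshold, n_trait)
        )

    if not per_trait:
        return []
    # one vectorized tail call for all traits' candidate terms
    all_k = np.concatenate([entry[2] for entry in per_trait])
    all_K = np.concatenate([entry[3] for entry in per_trait])
    all_n = np.concatenate([
        np.full(entry[2].size, entry[7]) for entry in per_trait
    ])
    all_p = np.atleast_1d(hypergeom.sf(all_k - 1, N_genome, all_K, all_n))
    bounds = np.cumsum([0] + [entry[2].size for entry in per_trait])
    per_trait = [
        entry[:4] + (all_p[bounds[i]:bounds[i + 1]],) + entry[5:]
        for i, entry in enumerate(per_trait)
    ]
    if config.global_bh:
        pooled = bh_adjust(np.concatenate([entry[4] for entry in per_trait]))
        offsets = np.cumsum([0] + [entry[4].size for entry in per_trait])
        adjusted = [pooled[offsets[i]:offsets[i + 1]] for i in range(len(per_trait))]
    else:
        adjusted = [bh_adjust(entry[4]) for entry in per_trait]

    links: list[TraitTermLink] = []
    for (trait, cand_idx, k, K, p_raw, occ, threshold, n_trait), p_adj in zip(
        per_trait, adjusted
    ):
        keep = (p_adj <= config.enrichment_fdr) & (occ >= threshold)
        trait_links = [
            TraitTermLink(
                trait_id=trait.trait_id,
                term_id=matrix.term_ids[cand_idx[j]],
                namespace=corpus.namespace,
                p_raw=float(p_raw[j]),
                p_adj=float(p_adj[j]),
                k_trait=int(k[j]),
                K_genome=int(K[j]),
                n_trait=n_trait,
                N_genome=N_genome,
                occ_regions=int(occ[j]),
                n_regions=trait.n_regions,
                trait_type=trait.trait_type,
            )
            for j in np.flatnonzero(keep)
        ]
        trait_links.sort(key=lambda l: (l.p_adj, l.term_id))
        links.extend(trait_links)
    links.sort(key=lambda l: l.trait_id)
    _assert_gates(links, corpus, config, total)
    return links


def _assert_gates(
    links: Sequence[TraitTermLink],
    corpus: AnnotationCorpus,
    config: PipelineConfig,
    n_total_genes: int,
) -> None:
    for link in links:
        assert link.p_adj <= config.enrichment_fdr
        assert link.occ_regions >= occurrence_threshold(
            link.n_regions, config.occurrence_fraction
        )
        assert generality_filter(
            corpus, link.term_id, config.generality_max_fraction, n_total_genes
        )


def links_summary(links: Sequence[TraitTermLink]) -> pd.DataFrame:
    """Per trait-type mean (sd) of link counts and unique-term totals."""
    frame = links_to_frame(links)
    rows = []
    for (trait_type, namespace), group in frame.groupby(["trait_type", "namespace"]):
        per_trait = group.groupby("trait_id").size()
        sd = float(per_trait.std(ddof=1)) if len(per_trait) > 1 else 0.0
        rows.append({
            "trait_type": trait_type,
            "namespace": namespace,
            "n_traits_linked": int(per_trait.size),
            "links_per_trait": f"{per_trait.mean():.1f} ({sd:.1f})",
            "n_links": int(len(group)),
            "n_unique_terms": int(group["term_id"].nunique()),
        })
    return pd.DataFrame(
        rows,
        columns=["trait_type", "namespace", "n_traits_linked",
                 "links_per_trait", "n_links", "n_unique_terms"],
    )


def links_to_frame(links: Sequence[TraitTermLink]) -> pd.DataFrame:
    columns = ["trait_id", "trait_type", "namespace", "term_id", "p_raw", "p_adj",
               "occ_regions", "n_regions", "k_trait", "K_genome", "n_trait",
               "N_genome"]
    return pd.DataFrame([{c: getattr(l, c) for c in columns} for l in links],
                        columns=columns)


def read_links_tsv(path: str) -> list[TraitTermLink]:
    frame = pd.read_csv(path, sep="\t", dtype={"trait_id": str, "term_id": str})
    fields = [f for f in TraitTermLink.__dataclass_fields__ if f in frame.columns]
    return [
        TraitTermLink(**{f: row[f] for f in fields})
        for _, row in frame.iterrows()
    ]


def write_links_tsv(
    links: Sequence[TraitTermLink], path: str, graph: OntologyGraph | None = None
) -> None:
    frame = links_to_frame(links)
    if graph is not None:
        frame.insert(
            4, "term_name",
            [graph.terms[t].name if t in graph.terms else "" for t in frame["term_id"]],
        )
    frame.to_csv(path, sep="\t", index=False)
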