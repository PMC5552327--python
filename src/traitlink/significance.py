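"""Permutation-based significance for trait-trait similarities.

Two schemes:

* ``random_regions`` — replace every trait's QTL regions by uniformly placed
  genome regions of identical number and length, rerun the entire pipeline
  (same filters, same code path) and count trait pairs at similarity
  thresholds.
* ``shuffled_links`` — randomly reassign ontology terms to traits while
  preserving the per-trait link counts and the global term multiset, and
  compare each trait's maximum similarity per target category to its null.

Permutation p-values use the add-one estimator ``(1 + #{null >= obs}) /
(n_reps + 1)``, which can never be 0; a tie-randomized variant (exactly
uniform under exchangeability, including for discrete statistics) is reported
alongside.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from traitlink.enrichment import TraitTermLink, bh_adjust
from traitlink.genome_qtl import GenomeIndex, QTLRegion, Trait
from traitlink.ontology import TermSimilarity
from traitlink.pipeline import (
    PipelineResources,
    pair_counts,
    run_similarity_pipeline,
)
from traitlink.trait_similarity import (
    MaxSimLink,
    build_similarity_matrix,
    max_similarity_links,
    term_sets_from_links,
)

logger = logging.getLogger(__name__)


@dataclass
class PermutationResult:
    scheme: str
    n_reps: int
    observed_stat: float
    null_stats: list[float]
    p_value: float
    p_randomized: float
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        assert len(self.null_stats) == self.n_reps
        assert 0 < self.p_value <= 1


def _perm_pvalues(
    observed: float, null_stats: Sequence[float], rng: np.random.Generator
) -> tuple[float, float]:
    null = np.asarray(null_stats, dtype=float)
    n = null.size
    greater = int((null > observed).sum())
    ties = int((null == observed).sum())
    p = (1 + greater + ties) / (n + 1)
    # tie-broken variant: rank the observed value uniformly among its ties,
    # giving an exactly discrete-uniform p on {1,...,n+1}/(n+1) under
    # exchangeability even when the statistic is integer-valued
    u = int(rng.integers(0, ties + 1))
    p_randomized = (greater + u + 1) / (n + 1)
    return p, float(p_randomized)


def sample_random_regions(
    genome: GenomeIndex, template_trait: Trait, rng: np.random.Generator
) -> list[QTLRegion]:
    """Random genome regions matching the template's region count and lengths.

    Placement is uniform over all (chromosome, start) pairs where the region
    fits; regions are drawn independently and may overlap.
    """
    chroms = genome.chromosomes
    lengths = np.array([genome.chrom_lengths[c] for c in chroms], dtype=np.int64)
    regions: list[QTLRegion] = []
    for idx, template in enumerate(template_trait.regions, start=1):
        slots = np.maximum(0, lengths - template.length + 1)
        total = int(slots.sum())
        if total == 0:
            raise ValueError(
                f"region of length {template.length} fits on no chromosome"
            )
        position = int(rng.integers(0, total))
        chrom_idx = int(np.searchsorted(np.cumsum(slots), position, side="right"))
        start = position - int(np.concatenate(([0], np.cumsum(slots)))[chrom_idx])
        regions.append(QTLRegion(
            region_id=f"{template_trait.trait_id}:perm{idx}",
            trait_id=template_trait.trait_id,
            chrom=chroms[chrom_idx],
            start=start,
            end=start + template.length,
        ))
    return regions


def randomize_dataset(
    dataset: Sequence[Trait], genome: GenomeIndex, rng: np.random.Generator
) -> list[Trait]:
    return [
        Trait(t.trait_id, t.trait_type, sample_random_regions(genome, t, rng))
        for t in dataset
    ]


def region_permutation_test(
    dataset: Sequence[Trait],
    resources: PipelineResources,
    thresholds: Sequence[float],
    n_reps: int,
    rng: np.random.Generator,
    *,
    pooled: bool = True,
    max_retries: int = 3,
) -> dict[tuple[str, float], PermutationResult]:
    """Scheme (i): pipeline reruns on random genome regions.

    The statistic is the number of trait pairs with similarity >= threshold,
    computed per namespace and (optionally) pooled over namespaces; the null
    reruns the identical pipeline entry point on randomized regions.
    """
    observed = run_similarity_pipeline(dataset, resources)
    keys = list(resources.namespaces) + (["pooled"] if pooled else [])

    def stats_of(outputs) -> dict[tuple[str, float], int]:
        stats: dict[tuple[str, float], int] = {}
        per_ns = {
            ns: pair_counts(outputs.matrices[ns], thresholds)
            for ns in resources.namespaces
        }
        for ns in resources.namespaces:
            for threshold, count in per_ns[ns].items():
                stats[(ns, threshold)] = count
        if pooled:
            for threshold in per_ns[resources.namespaces[0]]:
                stats[("pooled", threshold)] = sum(
                    per_ns[ns][threshold] for ns in resources.namespaces
                )
        return stats

    observed_stats = stats_of(observed)
    null_stats: dict[tuple[str, float], list[float]] = {
        key: [] for key in observed_stats
    }
    for rep in range(n_reps):
        for attempt in range(max_retries + 1):
            randomized = randomize_dataset(dataset, resources.genome, rng)
            try:
                outputs = run_similarity_pipeline(randomized, resources)
                break
            except Exception:  # noqa: BLE001 - rep retried with a fresh draw
                if attempt == max_retries:
                    raise
                logger.warning("permutation rep %d failed; retrying", rep)
        for key, value in stats_of(outputs).items():
            null_stats[key].append(float(value))

    results: dict[tuple[str, float], PermutationResult] = {}
    for key, nulls in null_stats.items():
        p, p_rand = _perm_pvalues(observed_stats[key], nulls, rng)
        results[key] = PermutationResult(
            scheme="random_regions",
            n_reps=n_reps,
            observed_stat=float(observed_stats[key]),
            null_stats=nulls,
            p_value=p,
            p_randomized=p_rand,
        )
    return results


def shuffle_trait_term_links(
    links: Sequence[TraitTermLink], rng: np.random.Generator, *, max_passes: int = 100
) -> list[TraitTermLink]:
    """Randomly reassign terms to trait-link slots.

    Preserves the per-trait link counts and the global term multiset. A trait
    receiving the same term twice is repaired by swapping with other slots;
    if repair is impossible the duplicates are kept with a warning.
    """
    if not links:
        raise ValueError("cannot shuffle an empty link list")
    from collections import Counter

    slots = list(links)
    trait_of = [link.trait_id for link in slots]
    terms = [slots[int(i)].term_id for i in rng.permutation(len(slots))]

    counts: dict[str, Counter] = {}
    for i, term in enumerate(terms):
        counts.setdefault(trait_of[i], Counter())[term] += 1

    def excess_slots() -> list[int]:
        seen: dict[str, set[str]] = {}
        out = []
        for i, term in enumerate(terms):
            bucket = seen.setdefault(trait_of[i], set())
            if term in bucket:
                out.append(i)
            else:
                bucket.add(term)
        return out

    for _ in range(max_passes):
        dupes = excess_slots()
        if not dupes:
            break
        fixed_any = False
        for i in dupes:
            t_i, x = trait_of[i], terms[i]
            for j in (int(j) for j in rng.permutation(len(terms))):
                t_j, y = trait_of[j], terms[j]
                # a swap removes the duplicate iff neither side re-creates one
                if t_j == t_i or y == x:
                    continue
                if counts[t_i][y] > 0 or counts[t_j][x] > 0:
                    continue
                terms[i], terms[j] = y, x
                counts[t_i][x] -= 1
                counts[t_i][y] += 1
                counts[t_j][y] -= 1
                counts[t_j][x] += 1
                fixed_any = True
                break
        if not fixed_any:
            break
    if excess_slots():
        logger.warning("could not fully de-duplicate shuffled links; keeping ties")
    return [replace(link, term_id=terms[i]) for i, link in enumerate(slots)]


def maxsim_link_significance(
    links: Sequence[TraitTermLink],
    termsim: TermSimilarity,
    namespace: str,
    n_reps: int,
    rng: np.random.Generator,
    fdr: float = 0.05,
    *,
    symmetric: bool = True,
) -> list[MaxSimLink]:
    """Scheme (ii): shuffled trait-term links as the null for max-similarity links.

    Per observed link, p = (1 + #{reps with randomized max similarity for that
    source/category >= observed}) / (n_reps + 1); BH across all links. The full
    annotated list is returned; filter on ``p_adj <= fdr`` for the significant
    network.
    """
    ns_links = [l for l in links if l.namespace == namespace]
    if not ns_links:
        raise ValueError(f"no links in namespace {namespace}")
    term_sets, trait_types = term_sets_from_links(ns_links, namespace)
    if len(term_sets) < 2:
        raise ValueError("need >= 2 linked traits for max-similarity significance")
    observed_matrix = build_similarity_matrix(
        term_sets, trait_types, namespace, termsim, symmetric=symmetric
    )
    observed = max_similarity_links(observed_matrix)
    exceed = {(l.source, l.target_category): 0 for l in observed}
    for _ in range(n_reps):
        shuffled = shuffle_trait_term_links(ns_links, rng)
        null_sets, null_types = term_sets_from_links(shuffled, namespace)
        null_matrix = build_similarity_matrix(
            null_sets, null_types, namespace, termsim, symmetric=symmetric
        )
        null_best: dict[tuple[str, str], float] = {
            (l.source, l.target_category): l.similarity
            for l in max_similarity_links(null_matrix)
        }
        for link in observed:
            key = (link.source, link.target_category)
            # a trait that lost all links in a rep contributes max similarity 0
            if null_best.get(key, 0.0) >= link.similarity - 1e-12:
                exceed[key] += 1
    p_values = [
        (1 + exceed[(l.source, l.target_category)]) / (n_reps + 1) for l in observed
    ]
    p_adj = bh_adjust(p_values)
    return [
        replace(link, p_perm=p, p_adj=q)
        for link, p, q in zip(observed, p_values, p_adj)
    ]


def significant_links(links: Sequence[MaxSimLink], fdr: float) -> list[MaxSimLink]:
    return [l for l in links if l.p_adj <= fdr]


def permutation_summary(
    results: Mapping[tuple[str, float], PermutationResult]
) -> pd.DataFrame:
    rows = []
    for (namespace, threshold), result in sorted(results.items()):
        null = np.asarray(result.null_stats)
        rows.append({
            "scheme": result.scheme,
            "namespace": namespace,
            "threshold": threshold,
            "observed": result.observed_stat,
            "null_mean": float(null.mean()) if null.size else float("nan"),
            "null_sd": float(null.std(ddof=1)) if null.size > 1 else 0.0,
            "p_value": result.p_value,
            "p_randomized": result.p_randomized,
            "n_reps": result.n_reps,
        })
    return pd.DataFrame(rows, columns=["scheme", "namespace", "threshold",
                                       "observed", "null_mean", "null_sd",
                                       "p_value", "p_randomized", "n_reps"])
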