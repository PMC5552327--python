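"""Trait-trait semantic similarity from per-trait term sets.

Set-level similarity is the best-match average (BMA): for each term of one set
the best-matching term of the other set is found, and the per-direction means
are averaged. With identical term sets every best match is the self match, so
the similarity is exactly 1.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from traitlink.enrichment import TraitTermLink
from traitlink.ontology import (
    AnnotationCorpus,
    LinTermSimilarity,
    OntologyGraph,
    TermSimilarity,
)

logger = logging.getLogger(__name__)


def best_match_average(
    terms_x: Sequence[str] | frozenset[str],
    terms_y: Sequence[str] | frozenset[str],
    termsim: TermSimilarity,
    *,
    symmetric: bool = True,
) -> float:
    """Best-match-average similarity of two non-empty term sets.

    Symmetric form (default): mean over both directional best-match means.
    ``symmetric=False`` gives the one-directional X-to-Y mean.
    """
    xs = sorted(set(terms_x))
    ys = sorted(set(terms_y))
    if not xs or not ys:
        raise ValueError("best_match_average requires non-empty term sets")
    sim = np.array([[termsim(x, y) for y in ys] for x in xs])
    forward = float(sim.max(axis=1).mean())
    if not symmetric:
        return forward
    backward = float(sim.max(axis=0).mean())
    return 0.5 * (forward + backward)


@dataclass
class TraitSimilarityMatrix:
    namespace: str
    trait_ids: list[str]
    values: np.ndarray
    trait_types: dict[str, str]
    term_sets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        n = len(self.trait_ids)
        assert self.values.shape == (n, n)
        self._index = {t: i for i, t in enumerate(self.trait_ids)}

    def similarity(self, trait_a: str, trait_b: str) -> float:
        return float(self.values[self._index[trait_a], self._index[trait_b]])

    @property
    def sim_max(self) -> float:
        """Maximum observed off-diagonal similarity (basis of the distance map)."""
        if len(self.trait_ids) < 2:
            return 0.0
        off = self.values[~np.eye(len(self.trait_ids), dtype=bool)]
        return float(off.max())

    def to_frame(self) -> pd.DataFrame:
        """Long-form table of all unordered trait pairs (including identity flag)."""
        rows = []
        for i, a in enumerate(self.trait_ids):
            for j in range(i + 1, len(self.trait_ids)):
                b = self.trait_ids[j]
                set_a = self.term_sets.get(a)
                set_b = self.term_sets.get(b)
                rows.append({
                    "trait_a": a,
                    "trait_b": b,
                    "namespace": self.namespace,
                    "similarity": float(self.values[i, j]),
                    "identical_term_sets": bool(set_a and set_a == set_b),
                })
        return pd.DataFrame(
            rows, columns=["trait_a", "trait_b", "namespace", "similarity",
                           "identical_term_sets"])


@dataclass(frozen=True)
class MaxSimLink:
    source: str
    target: str
    target_category: str
    similarity: float
    p_perm: float = float("nan")
    p_adj: float = float("nan")


def term_sets_from_links(
    links: Sequence[TraitTermLink], namespace: str
) -> tuple[dict[str, frozenset[str]], dict[str, str]]:
    """Group links of one namespace into per-trait term sets and type labels."""
    sets: dict[str, set[str]] = {}
    types: dict[str, str] = {}
    for link in links:
        if link.namespace != namespace:
            continue
        sets.setdefault(link.trait_id, set()).add(link.term_id)
        types[link.trait_id] = link.trait_type
    return {t: frozenset(s) for t, s in sets.items()}, types


def similarity_matrix(
    links: Sequence[TraitTermLink],
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    namespace: str,
    *,
    termsim: TermSimilarity | None = None,
    symmetric: bool = True,
) -> TraitSimilarityMatrix:
    """All-pairs BMA similarity among traits holding >= 1 link in the namespace."""
    term_sets, trait_types = term_sets_from_links(links, namespace)
    if len(term_sets) < 2:
        raise ValueError(
            f"need >= 2 traits with links in {namespace}, got {len(term_sets)}"
        )
    if termsim is None:
        termsim = LinTermSimilarity(corpus, graph)
    trait_ids = sorted(term_sets)
    return build_similarity_matrix(
        {t: term_sets[t] for t in trait_ids}, trait_types, namespace, termsim,
        symmetric=symmetric,
    )


def build_similarity_matrix(
    term_sets: Mapping[str, frozenset[str]],
    trait_types: Mapping[str, str],
    namespace: str,
    termsim: TermSimilarity,
    *,
    symmetric: bool = True,
) -> TraitSimilarityMatrix:
    """BMA matrix over explicit term sets (shared by observed and permuted runs)."""
    trait_ids = sorted(term_sets)
    n = len(trait_ids)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            value = best_match_average(
                term_sets[trait_ids[i]], term_sets[trait_ids[j]], termsim,
                symmetric=symmetric,
            )
            values[i, j] = values[j, i] = value
    for i, trait_id in enumerate(trait_ids):
        values[i, i] = best_match_average(
            term_sets[trait_id], term_sets[trait_id], termsim, symmetric=symmetric
        )
    return TraitSimilarityMatrix(
        namespace=namespace,
        trait_ids=trait_ids,
        values=values,
        trait_types=dict(trait_types),
        term_sets={t: frozenset(s) for t, s in term_sets.items()},
    )


def max_similarity_links(
    matrix: TraitSimilarityMatrix,
    trait_types: Mapping[str, str] | None = None,
) -> list[MaxSimLink]:
    """For every trait, the best-matching partner within each target category.

    Self pairs are excluded; ties go to the lexicographically smaller trait id.
    """
    if trait_types is None:
        trait_types = matrix.trait_types
    categories = sorted(set(trait_types.values()))
    links: list[MaxSimLink] = []
    for source in matrix.trait_ids:
        for category in categories:
            candidates = [
                t for t in matrix.trait_ids
                if t != source and trait_types[t] == category
            ]
            if not candidates:
                continue
            best = max(candidates,
                       key=lambda t: (matrix.similarity(source, t), _neg_key(t)))
            links.append(MaxSimLink(
                source=source,
                target=best,
                target_category=category,
                similarity=matrix.similarity(source, best),
            ))
    return links


def _neg_key(trait_id: str) -> tuple[int, ...]:
    # max() prefers larger keys; invert byte order so ties pick the smaller id
    return tuple(-b for b in trait_id.encode("utf-8"))


def f_bp(n_bp_links: int, n_mf_links: int) -> float:
    """Fraction of BP links among all BP + MF links of a trait."""
    total = n_bp_links + n_mf_links
    if total < 1:
        raise ValueError("f_bp undefined for a trait with zero links")
    return n_bp_links / total


def f_bp_per_trait(links: Sequence[TraitTermLink]) -> pd.DataFrame:
    """Per-trait f_BP over pooled BP and MF link lists (traits w/o links excluded)."""
    counts: dict[str, dict[str, int]] = {}
    types: dict[str, str] = {}
    for link in links:
        entry = counts.setdefault(link.trait_id, {"BP": 0, "MF": 0})
        if link.namespace in entry:
            entry[link.namespace] += 1
        types[link.trait_id] = link.trait_type
    rows = [
        {
            "trait_id": trait_id,
            "trait_type": types[trait_id],
            "n_bp": entry["BP"],
            "n_mf": entry["MF"],
            "f_bp": f_bp(entry["BP"], entry["MF"]),
        }
        for trait_id, entry in sorted(counts.items())
        if entry["BP"] + entry["MF"] >= 1
    ]
    return pd.DataFrame(rows, columns=["trait_id", "trait_type", "n_bp", "n_mf",
                                       "f_bp"])


def ks_two_sample(sample_a: Sequence[float],
                  sample_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Kolmogorov-Smirnov statistic and asymptotic p-value."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    result = ks_2samp(a, b, method="asymp")
    return float(result.statistic), float(result.pvalue)


def matrix_from_frame(frame: pd.DataFrame) -> TraitSimilarityMatrix:
    """Rebuild a similarity matrix from its long-form table (diagonal set to 1)."""
    namespaces = frame["namespace"].unique()
    if len(namespaces) != 1:
        raise ValueError("long-form table must hold exactly one namespace")
    trait_ids = sorted(set(frame["trait_a"]) | set(frame["trait_b"]))
    index = {t: i for i, t in enumerate(trait_ids)}
    values = np.eye(len(trait_ids))
    for row in frame.itertuples(index=False):
        i, j = index[row.trait_a], index[row.trait_b]
        values[i, j] = values[j, i] = row.similarity
    return TraitSimilarityMatrix(
        namespace=str(namespaces[0]),
        trait_ids=trait_ids,
        values=values,
        trait_types={},
        term_sets={},
    )


def write_similarity_tsv(matrix: TraitSimilarityMatrix, path: str) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False)


def write_maxsim_tsv(links: Sequence[MaxSimLink], path: str,
                     trait_types: Mapping[str, str] | None = None) -> None:
    rows = []
    for link in links:
        rows.append({
            "source": link.source,
            "source_type": (trait_types or {}).get(link.source, ""),
            "target": link.target,
            "target_category": link.target_category,
            "similarity": link.similarity,
            "p_perm": link.p_perm,
            "p_adj": link.p_adj,
        })
    pd.DataFrame(rows, columns=["source", "source_type", "target",
                                "target_category", "similarity", "p_perm",
                                "p_adj"]).to_csv(path, sep="\t", index=False)
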