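"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's own code paths: exact rational
hypergeometric tails, textbook BH step-up, and path-enumeration ancestor /
max-IC similarity computations on plain dicts.
"""

from __future__ import annotations

import math
from fractions import Fraction


def hypergeom_tail_exact(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), summed exactly with rationals."""
    denom = math.comb(N, n)
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), denom)
    return float(total)


def bh_textbook(p_values: list[float]) -> list[float]:
    """Step-up BH adjusted values, straight from the definition."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(1.0, p_values[i] * m / rank_from_top)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def ancestors_by_paths(parents: dict[str, list[str]], term: str) -> set[str]:
    """All terms reachable by enumerating every upward path (includes self)."""
    found = {term}
    frontier = [term]
    while frontier:
        current = frontier.pop()
        for parent in parents[current]:
            if parent not in found:
                found.add(parent)
                frontier.append(parent)
    return found


def lin_bruteforce(
    parents: dict[str, list[str]],
    direct: dict[str, set[str]],
    t1: str,
    t2: str,
) -> float:
    """Lin similarity via explicit propagation and max-IC common ancestor."""
    propagated = {
        gene: set().union(*(ancestors_by_paths(parents, t) for t in terms))
        for gene, terms in direct.items()
        if terms
    }
    counts: dict[str, int] = {}
    for terms in propagated.values():
        for term in terms:
            counts[term] = counts.get(term, 0) + 1
    n_genes = len(propagated)
    ic = {t: -math.log(c / n_genes) for t, c in counts.items()}
    common = ancestors_by_paths(parents, t1) & ancestors_by_paths(parents, t2)
    mica = max((ic[t] for t in common if t in ic), default=0.0)
    denom = ic[t1] + ic[t2]
    if denom == 0:
        return 0.0
    return min(1.0, 2 * mica / denom)


def random_dag_and_corpus(rng, n_terms: int = 30, n_genes: int = 20):
    """A random rooted DAG (term '0' root) plus random direct annotations."""
    parents: dict[str, list[str]] = {"0": []}
    for i in range(1, n_terms):
        n_parents = 1 + int(rng.random() < 0.3)
        choices = rng.choice(i, size=min(n_parents, i), replace=False)
        parents[str(i)] = [str(int(c)) for c in choices]
    direct: dict[str, set[str]] = {}
    for g in range(n_genes):
        k = 1 + int(rng.integers(0, 3))
        terms = rng.choice(n_terms, size=k, replace=False)
        direct[f"g{g}"] = {str(int(t)) for t in terms}
    return parents, direct
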