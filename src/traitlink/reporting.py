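"""Clustering and export: distance transform, complete-linkage dendrograms,
Newick trees, and SIF networks with node attributes."""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from traitlink.trait_similarity import MaxSimLink, TraitSimilarityMatrix


@dataclass(frozen=True)
class DendroNode:
    """A node of the merge tree; leaves carry a label, internals a merge height."""

    height: float
    children: tuple["DendroNode", ...] = ()
    label: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label or ""]
        out: list[str] = []
        for child in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class Dendrogram:
    root: DendroNode
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = sorted(self.root.leaves())

    def merge_heights(self) -> list[float]:
        heights: list[float] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                heights.append(node.height)
                stack.extend(node.children)
        return sorted(heights)


def similarity_to_distance(matrix: TraitSimilarityMatrix) -> np.ndarray:
    """Linear transform d = sim_max - sim with the diagonal forced to 0.

    ``sim_max`` is the maximum observed off-diagonal similarity, so the most
    similar trait pair is at distance 0 and the transform is order-reversing.
    """
    sim_max = matrix.sim_max
    dist = sim_max - matrix.values
    np.fill_diagonal(dist, 0.0)
    return dist


def complete_linkage(
    dist: np.ndarray, labels: Sequence[str] | None = None
) -> Dendrogram:
    """Agglomerative clustering with maximum-distance (complete) linkage.

    Ties between candidate merges are broken by the lexicographically smallest
    pair of cluster labels (a cluster is labelled by its smallest leaf), making
    the output deterministic.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n) or n < 2:
        raise ValueError("need a square distance matrix with n >= 2")
    if np.isnan(dist).any():
        raise ValueError("distance matrix contains NaN")
    if labels is None:
        labels = [str(i) for i in range(n)]
    if len(set(labels)) != n:
        raise ValueError("labels must be unique")

    nodes: dict[str, DendroNode] = {
        lab: DendroNode(height=0.0, label=lab) for lab in labels
    }
    members: dict[str, list[int]] = {lab: [i] for i, lab in enumerate(labels)}

    while len(nodes) > 1:
        best: tuple[float, str, str] | None = None
        keys = sorted(nodes)
        for ai, a in enumerate(keys):
            for b in keys[ai + 1:]:
                d = max(
                    dist[i, j] for i in members[a] for j in members[b]
                )
                candidate = (d, *sorted((a, b)))
                if best is None or candidate < best:
                    best = candidate
        d, a, b = best
        merged = DendroNode(height=float(d), children=(nodes[a], nodes[b]))
        key = min(a, b)
        other = max(a, b)
        nodes[key] = merged
        members[key] = members[a] + members[b]
        del nodes[other], members[other]

    return Dendrogram(root=next(iter(nodes.values())), labels=sorted(labels))


def _newick_label(label: str) -> str:
    if any(c in label for c in " ():,;'\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick_node(node: DendroNode, parent_height: float) -> str:
    branch = parent_height - node.height
    if node.is_leaf:
        return f"{_newick_label(node.label or '')}:{_format_len(parent_height)}"
    ordered = sorted(node.children, key=lambda c: min(c.leaves()))
    inner = ",".join(_newick_node(child, node.height) for child in ordered)
    return f"({inner}):{_format_len(branch)}"


def _format_len(value: float) -> str:
    text = f"{value:.10g}"
    return text if text != "-0" else "0"


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick text with branch lengths derived from merge heights.

    Leaf branches span from height 0 up to the parent merge; internal branches
    span between consecutive merge heights; children are ordered by smallest
    leaf label.
    """
    root = dendrogram.root
    if root.is_leaf:
        return f"{_newick_label(root.label or '')};"
    ordered = sorted(root.children, key=lambda c: min(c.leaves()))
    inner = ",".join(_newick_node(child, root.height) for child in ordered)
    return f"({inner});"


def parse_newick(text: str) -> DendroNode:
    """Parse a Newick string produced by :func:`to_newick` back into a tree.

    Node heights are reconstructed from branch lengths assuming an ultrametric
    tree (all leaves at height 0).
    """
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("Newick text must end with ';'")
    pos = 0
    body = text[:-1]

    def parse_node() -> tuple["_RawNode", None]:
        nonlocal pos
        if body[pos] == "(":
            pos += 1
            children = [parse_node()[0]]
            while body[pos] == ",":
                pos += 1
                children.append(parse_node()[0])
            if body[pos] != ")":
                raise ValueError(f"expected ')' at {pos}")
            pos += 1
            label = _read_label()
            branch = _read_branch()
            return _RawNode(label=label, branch=branch, children=children), None
        label = _read_label()
        branch = _read_branch()
        return _RawNode(label=label, branch=branch, children=[]), None

    def _read_label() -> str:
        nonlocal pos
        if pos < len(body) and body[pos] == "'":
            end = pos + 1
            out = []
            while end < len(body):
                if body[end] == "'" and end + 1 < len(body) and body[end + 1] == "'":
                    out.append("'")
                    end += 2
                elif body[end] == "'":
                    end += 1
                    break
                else:
                    out.append(body[end])
                    end += 1
            pos = end
            return "".join(out)
        start = pos
        while pos < len(body) and body[pos] not in ":,()":
            pos += 1
        return body[start:pos]

    def _read_branch() -> float:
        nonlocal pos
        if pos < len(body) and body[pos] == ":":
            pos += 1
            start = pos
            while pos < len(body) and body[pos] not in ",()":
                pos += 1
            return float(body[start:pos])
        return 0.0

    raw, _ = parse_node()
    if pos != len(body):
        raise ValueError("trailing characters in Newick text")
    return _raw_to_node(raw)


@dataclass
class _RawNode:
    label: str
    branch: float
    children: list["_RawNode"]

    def depth_to_leaf(self) -> float:
        if not self.children:
            return 0.0
        return max(c.branch + c.depth_to_leaf() for c in self.children)


def _raw_to_node(raw: _RawNode) -> DendroNode:
    if not raw.children:
        return DendroNode(height=0.0, label=raw.label)
    height = raw.depth_to_leaf()
    return DendroNode(
        height=height,
        children=tuple(_raw_to_node(c) for c in raw.children),
    )


def export_network(
    links: Sequence[MaxSimLink],
    trait_types: Mapping[str, str],
    relation: str = "sim",
) -> tuple[str, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Build SIF text plus node-attribute, edge-attribute and category-count tables.

    Links are undirected: A->B and B->A collapse to one edge. SIF itself has no
    weight column, so similarities travel in the edge-attribute table.
    """
    edges: dict[tuple[str, str], float] = {}
    for link in links:
        key = tuple(sorted((link.source, link.target)))
        edges.setdefault(key, link.similarity)
    sif_lines = [f"{a}\t{relation}\t{b}" for (a, b) in sorted(edges)]
    sif_text = "\n".join(sif_lines) + ("\n" if sif_lines else "")

    node_ids = sorted({n for pair in edges for n in pair})
    nodes = pd.DataFrame(
        [{"trait_id": n, "trait_type": trait_types.get(n, "")} for n in node_ids],
        columns=["trait_id", "trait_type"],
    )
    edge_rows = [
        {"trait_a": a, "trait_b": b, "similarity": sim}
        for (a, b), sim in sorted(edges.items())
    ]
    edge_frame = pd.DataFrame(edge_rows, columns=["trait_a", "trait_b", "similarity"])

    pair_counts: dict[tuple[str, str], int] = {}
    for (a, b) in edges:
        cat = tuple(sorted((trait_types.get(a, ""), trait_types.get(b, ""))))
        pair_counts[cat] = pair_counts.get(cat, 0) + 1
    counts = pd.DataFrame(
        [{"category_a": a, "category_b": b, "n_links": n}
         for (a, b), n in sorted(pair_counts.items())],
        columns=["category_a", "category_b", "n_links"],
    )
    return sif_text, nodes, edge_frame, counts
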