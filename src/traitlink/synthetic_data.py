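"""Synthetic ontology/genome/annotation/QTL generator with planted structure.

Every pipeline stage can be exercised without external data: the generator
emits a rooted DAG ontology per namespace (valid OBO), a tiled gene layout
(GFF3), power-law background annotations (TSV), and QTL region tables in which
*planted* traits have regions centered on genes carrying rare signal terms.
Traits in one planted group receive distinct sibling leaf terms under a shared
anchor term, so in-group trait pairs have a known, high semantic similarity.
All outputs are deterministic given the seed.
"""

from __future__ import annotations

import io
from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from traitlink.genome_qtl import GeneLocus, Trait, load_qtl_table
from traitlink.ontology import OntologyGraph, parse_obo

_NS_META = {
    "BP": ("biological_process", "B"),
    "MF": ("molecular_function", "M"),
    "CC": ("cellular_component", "C"),
}


@dataclass(frozen=True)
class PlantedGroup:
    """A group of traits sharing semantically close planted signal terms.

    Each trait in the group gets ``n_signal_terms`` private leaf terms (per
    namespace) under one shared anchor term; each of the trait's regions is,
    with ``planting_probability``, centered on a gene carrying one of its
    signal terms (``multiplicity`` carrier genes per region and term).
    """

    name: str
    n_traits: int = 2
    trait_type: str = "macroscopic"
    n_regions: int = 4
    n_signal_terms: int = 1
    planting_probability: float = 1.0
    multiplicity: int = 1


@dataclass
class SyntheticSpec:
    n_terms: int = 150  # per namespace
    branching: int = 3
    depth: int = 5
    diamond_fraction: float = 0.1
    n_genes: int = 500
    n_chromosomes: int = 5
    gene_length: int = 2_000
    gene_spacing: int = 3_000
    annotation_rate: float = 3.0
    powerlaw_exponent: float = 1.5
    n_traits: dict[str, int] = field(
        default_factory=lambda: {"macroscopic": 4, "metabolite": 3, "expression": 3}
    )
    regions_per_trait: tuple[int, int] = (2, 5)
    region_length: tuple[int, int] = (40_000, 80_000)
    planted: list[PlantedGroup] = field(default_factory=list)
    # minimum bp gap between one trait's regions (0 = unconstrained placement,
    # exchangeable with the random-region permutation sampler)
    region_min_gap: int = 0
    namespaces: tuple[str, ...] = ("BP", "MF")
    generality_max_fraction: float = 0.01  # used only to warn about hot signals
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.branching < 1 or self.depth < 1:
            raise ValueError("branching and depth must be >= 1")
        for name in ("n_terms", "n_genes", "n_chromosomes", "gene_length",
                     "gene_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def chrom_capacity(self) -> int:
        return -(-self.n_genes // self.n_chromosomes)

    @property
    def chrom_length(self) -> int:
        return self.chrom_capacity * (self.gene_length + self.gene_spacing)


@dataclass
class SyntheticDataset:
    """All generated artifacts, as text plus parsed convenience objects."""

    spec: SyntheticSpec
    obo_text: str
    gff3_text: str
    annotation_tsv: dict[str, str]
    qtl_tsv: str
    ground_truth: pd.DataFrame
    genes: list[GeneLocus]

    @property
    def traits(self) -> list[Trait]:
        # the production reader accepts file-like objects, keeping generated
        # tables round-trippable without touching disk
        return load_qtl_table(io.StringIO(self.qtl_tsv))

    def load(self, config=None):
        """Round-trip through the production readers into pipeline inputs.

        Returns ``(traits, resources)`` where resources bundle the parsed
        ontology, per-namespace corpora and the genome index.
        """
        import tempfile

        from traitlink.genome_qtl import PipelineConfig, load_genome
        from traitlink.ontology import (
            parse_obo,
            propagate_annotations,
            read_annotation_tsv,
        )
        from traitlink.pipeline import PipelineResources

        if config is None:
            config = PipelineConfig()
        with tempfile.TemporaryDirectory() as tmp:
            paths = self.write(tmp)
            graph = parse_obo(str(paths["obo"]))
            genes = load_genome(str(paths["gff3"]))
            corpora = {}
            graphs = {}
            for namespace in self.spec.namespaces:
                direct = read_annotation_tsv(str(paths[f"annotations_{namespace}"]))
                corpora[namespace] = propagate_annotations(
                    graph, direct, namespace=namespace
                )
                graphs[namespace] = graph
            traits = load_qtl_table(str(paths["qtl"]))
        resources = PipelineResources.build(genes, graphs, corpora, config)
        return traits, resources

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "obo": outdir / "ontology.obo",
            "gff3": outdir / "genome.gff3",
            "qtl": outdir / "qtl_regions.tsv",
            "ground_truth": outdir / "ground_truth.tsv",
        }
        paths["obo"].write_text(self.obo_text, encoding="utf-8")
        paths["gff3"].write_text(self.gff3_text, encoding="utf-8")
        paths["qtl"].write_text(self.qtl_tsv, encoding="utf-8")
        self.ground_truth.to_csv(paths["ground_truth"], sep="\t", index=False)
        for namespace, text in self.annotation_tsv.items():
            key = f"annotations_{namespace}"
            paths[key] = outdir / f"annotations_{namespace.lower()}.tsv"
            paths[key].write_text(text, encoding="utf-8")
        return paths


def benchmark_spec(
    *,
    planting_probability: float = 1.0,
    n_planted_groups: int = 5,
    scale: float = 1.0,
    n_signal_terms: int = 3,
    branching: int = 6,
) -> SyntheticSpec:
    """The planted-recovery benchmark design (30 traits, 10 of them planted).

    Planted traits come in groups of two sharing an anchor; background term
    carriers are genomically clustered and carrier blocks are kept apart, so
    the dominant false-positive channels (multi-region cluster hits, regions
    straddling foreign carrier blocks) are controlled. ``scale`` shrinks the
    term/gene/trait counts proportionally for faster runs;
    ``planting_probability=0`` yields a pure-null dataset (carrier genes still
    annotated, regions placed at random) with unconstrained region placement,
    exchangeable with the random-region permutation sampler.
    """
    def s(x: int) -> int:
        return max(2, int(round(x * scale)))

    null_counts = {"macroscopic": s(8), "metabolite": s(6), "expression": s(6)}
    return SyntheticSpec(
        n_terms=s(200),
        branching=branching,
        depth=5,
        n_genes=s(500),
        n_chromosomes=5,
        gene_length=2_000,
        gene_spacing=5_000,
        annotation_rate=3.0,
        powerlaw_exponent=1.5,
        n_traits=null_counts,
        regions_per_trait=(3, 5),
        region_length=(15_000, 25_000),
        region_min_gap=0 if planting_probability == 0 else 100_000,
        planted=[
            PlantedGroup(
                name=f"grp{i}",
                n_traits=2,
                trait_type=("macroscopic", "metabolite", "expression")[i % 3],
                n_regions=4,
                n_signal_terms=n_signal_terms,
                planting_probability=planting_probability,
            )
            for i in range(n_planted_groups)
        ],
    )


def _term_id(namespace: str, index: int) -> str:
    return f"SYN:{_NS_META[namespace][1]}{index:06d}"


def generate_ontology(spec: SyntheticSpec, rng: np.random.Generator) -> str:
    """Emit a valid OBO file with one rooted DAG of ``n_terms`` per namespace.

    Terms are grown level by level with ``branching`` children per parent on
    average; a ``diamond_fraction`` of non-root terms get a second parent from
    a strictly shallower level, creating diamond motifs.
    """
    chunks = ["format-version: 1.2\nontology: synthetic\n"]
    for namespace in spec.namespaces:
        obo_ns, _ = _NS_META[namespace]
        parents: dict[int, list[int]] = {0: []}
        depth_of = {0: 0}
        levels: dict[int, list[int]] = {0: [0]}
        next_id = 1
        level = 0
        while next_id < spec.n_terms:
            level = min(level + 1, spec.depth)
            parent_pool = levels[level - 1] if level - 1 in levels else levels[level]
            capacity = len(parent_pool) * spec.branching
            count = min(capacity, spec.n_terms - next_id)
            ids = list(range(next_id, next_id + count))
            next_id += count
            # children fill shuffled parents in chunks of `branching`, so leaf
            # clusters of that size exist for signal-term selection
            shuffled = [int(parent_pool[int(i)])
                        for i in rng.permutation(len(parent_pool))]
            for offset, term in enumerate(ids):
                parent = shuffled[offset // spec.branching]
                parents[term] = [parent]
                depth_of[term] = depth_of[parent] + 1
                if depth_of[term] > 1 and rng.random() < spec.diamond_fraction:
                    shallow = [
                        t for d in range(depth_of[term])
                        for t in levels.get(d, [])
                        if t != parent
                    ]
                    if shallow:
                        extra = int(shallow[rng.integers(0, len(shallow))])
                        parents[term].append(extra)
                levels.setdefault(depth_of[term], []).append(term)
        for term in range(spec.n_terms):
            term_id = _term_id(namespace, term)
            name = (
                f"{obo_ns} root" if term == 0
                else f"synthetic {obo_ns} term {term}"
            )
            stanza = [f"[Term]", f"id: {term_id}", f"name: {name}",
                      f"namespace: {obo_ns}"]
            for parent in parents[term]:
                stanza.append(f"is_a: {_term_id(namespace, parent)}")
            chunks.append("\n".join(stanza) + "\n")
    return "\n".join(chunks)


def _leaf_clusters(graph: OntologyGraph, namespace: str) -> dict[str, list[str]]:
    """Map each term to its single-parent leaf children (candidate signal leaves)."""
    has_child: set[str] = set()
    for term in graph.terms.values():
        has_child.update(term.parent_ids)
    clusters: dict[str, list[str]] = {}
    for term in graph.terms.values():
        if term.namespace != namespace or term.obsolete:
            continue
        if term.term_id in has_child or len(term.parent_ids) != 1:
            continue
        (parent,) = term.parent_ids
        clusters.setdefault(parent, []).append(term.term_id)
    return {parent: sorted(leaves) for parent, leaves in clusters.items()}


def choose_signal_terms(
    graph: OntologyGraph, spec: SyntheticSpec, rng: np.random.Generator
) -> dict[str, dict[str, list[list[str]]]]:
    """Pick per-group anchors and per-trait sibling leaf terms per namespace.

    Returns ``signals[group.name][namespace]`` = list (one entry per trait in
    the group) of signal term lists. Groups get disjoint anchors; a group's
    leaves are all children of its anchor.
    """
    signals: dict[str, dict[str, list[list[str]]]] = {}
    for namespace in spec.namespaces:
        clusters = _leaf_clusters(graph, namespace)
        used: set[str] = set()
        candidates = sorted(clusters)
        order = rng.permutation(len(candidates))
        queue = [candidates[int(i)] for i in order]
        for group in spec.planted:
            needed = group.n_traits * group.n_signal_terms
            anchor = next(
                (a for a in queue
                 if a not in used and len(clusters[a]) >= needed),
                None,
            )
            if anchor is None:
                raise ValueError(
                    f"ontology has no free anchor with {needed} leaf children "
                    f"for group {group.name!r} in {namespace}; increase n_terms "
                    "or branching"
                )
            used.add(anchor)
            leaves = clusters[anchor][:needed]
            per_trait = [
                leaves[i * group.n_signal_terms:(i + 1) * group.n_signal_terms]
                for i in range(group.n_traits)
            ]
            signals.setdefault(group.name, {})[namespace] = per_trait
    return signals


def _tile_genes(spec: SyntheticSpec) -> list[GeneLocus]:
    genes: list[GeneLocus] = []
    pitch = spec.gene_length + spec.gene_spacing
    for i in range(spec.n_genes):
        chrom = i // spec.chrom_capacity
        slot = i % spec.chrom_capacity
        start = slot * pitch
        genes.append(GeneLocus(
            gene_id=f"g{i:05d}",
            chrom=f"chr{chrom + 1}",
            start=start,
            end=start + spec.gene_length,
            strand="+" if i % 2 == 0 else "-",
        ))
    return genes


def generate_genome_and_annotations(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    *,
    graph: OntologyGraph | None = None,
    carriers: dict[str, dict[str, list[int]]] | None = None,
) -> tuple[str, dict[str, str]]:
    """Tile genes on chromosomes and draw power-law background annotations.

    ``carriers`` (namespace -> signal term -> gene indices) injects the planted
    signal annotations and removes those terms from the background pool; the
    plain two-argument call generates a pure background dataset.
    """
    genes = _tile_genes(spec)
    gff3 = io.StringIO()
    gff3.write("##gff-version 3\n")
    for gene in genes:
        strand = gene.strand if gene.strand in {"+", "-"} else "."
        gff3.write(
            f"{gene.chrom}\tsynthetic\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
            f"{strand}\t.\tID={gene.gene_id}\n"
        )

    annotation_tsv: dict[str, str] = {}
    for namespace in spec.namespaces:
        signal_map = (carriers or {}).get(namespace, {})
        signal_terms = set(signal_map)
        pool = [
            _term_id(namespace, i) for i in range(1, spec.n_terms)
            if _term_id(namespace, i) not in signal_terms
        ]
        # power-law term frequencies: the total annotation budget
        # (annotation_rate * n_genes) is split over terms with weight
        # (rank+1)^-alpha, ranks assigned to terms in random order; each
        # term's carrier genes are drawn from a compact genomic window,
        # mimicking clustered gene families
        ranks = rng.permutation(len(pool))
        weights = (ranks + 1.0) ** -spec.powerlaw_exponent
        weights /= weights.sum()
        total = int(round(spec.annotation_rate * spec.n_genes))
        counts = rng.multinomial(total, weights)
        annotations: dict[str, set[str]] = {g.gene_id: set() for g in genes}
        for j, term in enumerate(pool):
            k = min(int(counts[j]), spec.n_genes)
            if k == 0:
                continue
            window = min(spec.n_genes, max(k, 2 * k))
            start = int(rng.integers(0, spec.n_genes - window + 1))
            chosen = rng.choice(window, size=k, replace=False)
            for c in chosen:
                annotations[genes[start + int(c)].gene_id].add(term)
        for term in sorted(signal_map):
            for gene_idx in sorted(signal_map[term]):
                annotations[genes[gene_idx].gene_id].add(term)
        lines = ["gene_id\tterm_id"]
        for gene in genes:
            for term in sorted(annotations[gene.gene_id]):
                lines.append(f"{gene.gene_id}\t{term}")
        annotation_tsv[namespace] = "\n".join(lines) + "\n"
    return gff3.getvalue(), annotation_tsv


def generate_qtl_dataset(
    spec: SyntheticSpec,
    genes: Sequence[GeneLocus],
    carriers: dict[str, dict[str, list[int]]],
    signals: dict[str, dict[str, list[list[str]]]],
    rng: np.random.Generator,
) -> tuple[str, pd.DataFrame]:
    """Draw QTL regions for null traits and carrier-centered regions for
    planted traits; return the QTL TSV and the ground-truth table."""
    gene_list = list(genes)
    chrom_length = spec.chrom_length
    lo, hi = spec.region_length

    def random_region() -> tuple[str, int, int]:
        length = int(rng.integers(lo, hi + 1))
        length = min(length, chrom_length)
        chrom = f"chr{int(rng.integers(0, spec.n_chromosomes)) + 1}"
        start = int(rng.integers(0, chrom_length - length + 1))
        return chrom, start, start + length

    def centered_region(block: Sequence[int]) -> tuple[str, int, int]:
        first, last = gene_list[block[0]], gene_list[block[-1]]
        span = last.end - first.start
        length = int(rng.integers(lo, hi + 1))
        length = max(min(length, chrom_length), min(span, chrom_length))
        center = (first.start + last.end) // 2
        start = max(0, min(center - length // 2, chrom_length - length))
        return first.chrom, start, start + length

    def far_enough(region: tuple[str, int, int],
                   placed: list[tuple[str, int, int]]) -> bool:
        gap = spec.region_min_gap
        for other in placed:
            if other[0] != region[0]:
                continue
            if region[1] < other[2] + gap and other[1] < region[2] + gap:
                return False
        return True

    def place(draw, placed: list[tuple[str, int, int]], max_tries: int = 200):
        region = draw()
        if spec.region_min_gap > 0:
            for _ in range(max_tries):
                if far_enough(region, placed):
                    break
                region = draw()
        placed.append(region)
        return region

    rows: list[str] = ["trait_id\ttrait_type\tchrom\tstart\tend"]
    truth_rows: list[dict] = []

    for group in spec.planted:
        for t in range(group.n_traits):
            trait_id = f"{group.name}_t{t + 1}"
            placed: list[tuple[str, int, int]] = []
            # region r is planted iff the Bernoulli draw succeeds; planted
            # regions are centered on the trait's carrier genes for region r
            for r in range(group.n_regions):
                planted = rng.random() < group.planting_probability
                if planted:
                    namespace = spec.namespaces[0]
                    term = signals[group.name][namespace][t][0]
                    m = group.multiplicity
                    block = carriers[namespace][term][r * m:(r + 1) * m]
                    chrom, start, end = centered_region(block)
                    placed.append((chrom, start, end))
                else:
                    chrom, start, end = place(random_region, placed)
                rows.append(
                    f"{trait_id}\t{group.trait_type}\t{chrom}\t{start}\t{end}"
                )
            for namespace in spec.namespaces:
                for term in signals[group.name][namespace][t]:
                    truth_rows.append({
                        "trait_id": trait_id,
                        "trait_type": group.trait_type,
                        "group": group.name,
                        "namespace": namespace,
                        "term_id": term,
                        "n_regions": group.n_regions,
                        "planting_probability": group.planting_probability,
                    })

    for trait_type in sorted(spec.n_traits):
        for i in range(spec.n_traits[trait_type]):
            trait_id = f"null_{trait_type}_{i + 1:03d}"
            k = int(rng.integers(spec.regions_per_trait[0],
                                 spec.regions_per_trait[1] + 1))
            placed = []
            for _ in range(k):
                chrom, start, end = place(random_region, placed)
                rows.append(f"{trait_id}\t{trait_type}\t{chrom}\t{start}\t{end}")

    truth = pd.DataFrame(
        truth_rows,
        columns=["trait_id", "trait_type", "group", "namespace", "term_id",
                 "n_regions", "planting_probability"],
    )
    return "\n".join(rows) + "\n", truth


def _assign_carriers(
    spec: SyntheticSpec,
    signals: dict[str, dict[str, list[list[str]]]],
    rng: np.random.Generator,
) -> dict[str, dict[str, list[int]]]:
    """Choose carrier gene blocks for every signal term.

    Each signal term needs ``n_regions`` blocks of ``multiplicity`` adjacent
    genes (one block per potential planted region, so a region centered on a
    block covers all its carriers). A trait's signal terms across namespaces
    share the same carriers, so one planted region serves both BP and MF;
    carriers are disjoint across traits.
    """
    carriers: dict[str, dict[str, list[int]]] = {ns: {} for ns in spec.namespaces}
    taken: set[int] = set()
    import warnings

    for group in spec.planted:
        n_carriers = group.n_regions * group.multiplicity
        if n_carriers > spec.generality_max_fraction * spec.n_genes:
            warnings.warn(
                f"group {group.name!r}: signal terms annotate {n_carriers} genes, "
                f"above the generality cutoff "
                f"({spec.generality_max_fraction:.0%} of {spec.n_genes}); the "
                "pipeline will reject them",
                stacklevel=2,
            )
        # keep carrier blocks farther apart than half the maximum region
        # length, so a region centered on one block cannot cover another
        pitch = spec.gene_length + spec.gene_spacing
        margin = spec.region_length[1] // 2 // pitch + 2
        for t in range(group.n_traits):
            picked: list[int] = []
            for _ in range(group.n_regions):
                block = _free_block(spec, group.multiplicity, taken, rng)
                taken.update(range(block[0] - margin, block[-1] + margin + 1))
                picked.extend(block)
            for namespace in spec.namespaces:
                for term in signals[group.name][namespace][t]:
                    carriers[namespace][term] = picked
    return carriers


def _free_block(
    spec: SyntheticSpec, size: int, taken: set[int], rng: np.random.Generator,
    max_tries: int = 10_000,
) -> list[int]:
    """A run of ``size`` adjacent free gene indices on one chromosome."""
    capacity = spec.chrom_capacity
    for _ in range(max_tries):
        start = int(rng.integers(0, spec.n_genes - size + 1))
        block = list(range(start, start + size))
        if block[-1] >= spec.n_genes:
            continue
        if start // capacity != block[-1] // capacity:
            continue  # block must not straddle a chromosome boundary
        if any(i in taken for i in block):
            continue
        return block
    raise ValueError("not enough free adjacent genes to host signal carriers")


def generate_dataset(spec: SyntheticSpec, seed: int | None = None) -> SyntheticDataset:
    """End-to-end generation: ontology, signals, genome, annotations, QTL, truth."""
    if seed is None:
        seed = spec.rng_seed
    root = np.random.SeedSequence(seed)
    rng_onto, rng_sig, rng_ann, rng_qtl = (
        np.random.default_rng(s) for s in root.spawn(4)
    )
    obo_text = generate_ontology(spec, rng_onto)
    graph = _parse_obo_text(obo_text)
    signals = choose_signal_terms(graph, spec, rng_sig) if spec.planted else {}
    carriers = _assign_carriers(spec, signals, rng_sig) if spec.planted else {}
    gff3_text, annotation_tsv = generate_genome_and_annotations(
        spec, rng_ann, graph=graph, carriers=carriers
    )
    genes = _tile_genes(spec)
    qtl_tsv, truth = generate_qtl_dataset(spec, genes, carriers, signals, rng_qtl)
    return SyntheticDataset(
        spec=spec,
        obo_text=obo_text,
        gff3_text=gff3_text,
        annotation_tsv=annotation_tsv,
        qtl_tsv=qtl_tsv,
        ground_truth=truth,
        genes=genes,
    )


def _parse_obo_text(text: str) -> OntologyGraph:
    import tempfile

    with tempfile.NamedTemporaryFile(
        "w", suffix=".obo", delete=False, encoding="utf-8"
    ) as handle:
        handle.write(text)
        path = handle.name
    try:
        return parse_obo(path)
    finally:
        Path(path).unlink(missing_ok=True)
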