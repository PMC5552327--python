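"""Genome gene coordinates, QTL region tables, region-to-gene mapping and filters.

Coordinates are stored 0-based half-open throughout; GFF3 input (1-based
inclusive) is converted on ingestion and re-emitted natively on output. A gene
belongs to a region if they overlap by at least 1 bp.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

TRAIT_TYPES = ("macroscopic", "metabolite", "expression")


@dataclass(frozen=True)
class GeneLocus:
    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} must be < end {self.end}"
            )


@dataclass
class QTLRegion:
    region_id: str
    trait_id: str
    chrom: str
    start: int
    end: int
    gene_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"region {self.region_id}: start {self.start} must be < end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Trait:
    trait_id: str
    trait_type: str
    regions: list[QTLRegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in TRAIT_TYPES:
            raise ValueError(
                f"trait {self.trait_id}: unknown trait_type {self.trait_type!r}"
            )

    @property
    def gene_ids(self) -> frozenset[str]:
        """Deduplicated union of gene sets over this trait's regions."""
        out: set[str] = set()
        for region in self.regions:
            out |= region.gene_ids
        return frozenset(out)

    @property
    def n_regions(self) -> int:
        return len(self.regions)


@dataclass
class PipelineConfig:
    """All pipeline thresholds, defaulting to the published settings."""

    region_gene_cap: int = 450
    min_regions: dict[str, int] = field(
        default_factory=lambda: {"macroscopic": 2, "metabolite": 2, "expression": 3}
    )
    occurrence_fraction: float = 0.5
    generality_max_fraction: float = 0.01
    enrichment_fdr: float = 0.1
    linkage_fdr: float = 0.05
    n_permutations: int = 1000
    rng_seed: int = 0
    # one-based QTL table coordinates converted on ingestion when set
    qtl_coordinates_one_based: bool = False
    # BH within each trait's candidate terms (default) or across all tests
    global_bh: bool = False
    # symmetric best-match average (default) vs the one-directional variant
    symmetric_bma: bool = True
    term_similarity: str = "lin"
    propagate_part_of: bool = True

    def __post_init__(self) -> None:
        for name in ("occurrence_fraction", "generality_max_fraction",
                     "enrichment_fdr", "linkage_fdr"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {value}")
        for name in ("region_gene_cap", "n_permutations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for trait_type, count in self.min_regions.items():
            if trait_type not in TRAIT_TYPES:
                raise ValueError(f"min_regions: unknown trait type {trait_type!r}")
            if count <= 0:
                raise ValueError("min_regions counts must be positive")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


class GenomeIndex:
    """Per-chromosome interval index over gene loci for overlap queries."""

    def __init__(self, genes: Iterable[GeneLocus],
                 chrom_lengths: Mapping[str, int] | None = None):
        self.genes: dict[str, GeneLocus] = {}
        by_chrom: dict[str, list[GeneLocus]] = {}
        for gene in genes:
            if gene.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {gene.gene_id!r}")
            self.genes[gene.gene_id] = gene
            by_chrom.setdefault(gene.chrom, []).append(gene)
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._ids: dict[str, list[str]] = {}
        self._max_end_prefix: dict[str, np.ndarray] = {}
        for chrom, loci in by_chrom.items():
            loci.sort(key=lambda g: (g.start, g.end, g.gene_id))
            self._starts[chrom] = np.array([g.start for g in loci], dtype=np.int64)
            ends = np.array([g.end for g in loci], dtype=np.int64)
            self._ends[chrom] = ends
            self._ids[chrom] = [g.gene_id for g in loci]
            self._max_end_prefix[chrom] = np.maximum.accumulate(ends)
        if chrom_lengths is not None:
            self.chrom_lengths = dict(chrom_lengths)
        else:
            self.chrom_lengths = {
                chrom: int(self._ends[chrom].max()) for chrom in self._ends
            }

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.chrom_lengths)

    def __len__(self) -> int:
        return len(self.genes)

    def overlapping(self, chrom: str, start: int, end: int) -> frozenset[str]:
        """Gene ids with >= 1 bp overlap with [start, end) on ``chrom``."""
        if chrom not in self._starts:
            logger.warning("query on unknown chromosome %r", chrom)
            return frozenset()
        starts = self._starts[chrom]
        hi = int(np.searchsorted(starts, end, side="left"))
        if hi == 0:
            return frozenset()
        # genes are short relative to chromosomes; prefix max-end prunes the scan
        max_ends = self._max_end_prefix[chrom]
        lo = int(np.searchsorted(max_ends[:hi], start, side="right"))
        ends = self._ends[chrom]
        ids = self._ids[chrom]
        return frozenset(
            ids[i] for i in range(lo, hi) if ends[i] > start
        )


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attr.strip().split(";"):
        if "=" in item:
            key, value = item.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def load_genome(path: str, format: str | None = None) -> list[GeneLocus]:
    """Load gene loci from GFF3 (``gene`` features) or BED4+.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open;
    BED is passed through. Duplicate gene ids are fatal.
    """
    if format is None:
        lowered = path.lower()
        if lowered.endswith((".gff", ".gff3")):
            format = "GFF3"
        elif lowered.endswith(".bed"):
            format = "BED"
        else:
            raise ValueError(f"cannot infer format of {path!r}; pass format=")
    format = format.upper()
    if format not in {"GFF3", "BED"}:
        raise ValueError(f"unsupported genome format {format!r}")

    genes: list[GeneLocus] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if format == "GFF3":
                    if len(fields) < 9:
                        raise ValueError("expected 9 GFF3 columns")
                    if fields[2] != "gene":
                        continue
                    chrom = fields[0]
                    start = int(fields[3]) - 1
                    end = int(fields[4])
                    strand = fields[6] if fields[6] in {"+", "-"} else "unknown"
                    attrs = _parse_gff3_attributes(fields[8])
                    gene_id = attrs.get("ID") or attrs.get("Name")
                    if not gene_id:
                        raise ValueError("gene row without ID attribute")
                else:
                    if len(fields) < 4:
                        raise ValueError("expected BED4+ columns")
                    chrom = fields[0]
                    start = int(fields[1])
                    end = int(fields[2])
                    gene_id = fields[3]
                    strand = (
                        fields[5] if len(fields) > 5 and fields[5] in {"+", "-"}
                        else "unknown"
                    )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            genes.append(GeneLocus(gene_id, chrom, start, end, strand))
    return genes


def write_genome_gff3(genes: Sequence[GeneLocus], path: str) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("##gff-version 3\n")
        for gene in genes:
            strand = gene.strand if gene.strand in {"+", "-"} else "."
            handle.write(
                f"{gene.chrom}\tsynthetic\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                f"{strand}\t.\tID={gene.gene_id}\n"
            )


def write_genome_bed(genes: Sequence[GeneLocus], path: str) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for gene in genes:
            strand = gene.strand if gene.strand in {"+", "-"} else "."
            handle.write(
                f"{gene.chrom}\t{gene.start}\t{gene.end}\t{gene.gene_id}\t0\t{strand}\n"
            )


def genes_in_region(
    genes: GenomeIndex | Iterable[GeneLocus], region: QTLRegion
) -> frozenset[str]:
    """Ids of genes overlapping the region by >= 1 bp (any-overlap rule)."""
    index = genes if isinstance(genes, GenomeIndex) else GenomeIndex(genes)
    return index.overlapping(region.chrom, region.start, region.end)


def load_qtl_table(path: str, *, one_based: bool = False) -> list[Trait]:
    """Read a QTL region TSV with header trait_id, trait_type, chrom, start, end."""
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str, "trait_id": str})
    required = {"trait_id", "trait_type", "chrom", "start", "end"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing QTL table columns {sorted(missing)}")
    traits: dict[str, Trait] = {}
    counters: dict[str, int] = {}
    for row in table.itertuples(index=False):
        start = int(row.start) - 1 if one_based else int(row.start)
        end = int(row.end)
        trait = traits.get(row.trait_id)
        if trait is None:
            trait = Trait(trait_id=row.trait_id, trait_type=row.trait_type)
            traits[row.trait_id] = trait
        elif trait.trait_type != row.trait_type:
            raise ValueError(
                f"{path}: trait {row.trait_id} has conflicting trait_type values"
            )
        counters[row.trait_id] = counters.get(row.trait_id, 0) + 1
        region_id = f"{row.trait_id}:{counters[row.trait_id]}"
        trait.regions.append(
            QTLRegion(region_id, row.trait_id, str(row.chrom), start, end)
        )
    dataset = [traits[tid] for tid in sorted(traits)]
    _log_region_overlaps(dataset)
    return dataset


def _log_region_overlaps(dataset: Sequence[Trait]) -> None:
    # overlapping regions of one trait are kept distinct; occurrence counting
    # uses regions as given, so overlaps are only reported
    for trait in dataset:
        by_chrom: dict[str, list[QTLRegion]] = {}
        for region in trait.regions:
            by_chrom.setdefault(region.chrom, []).append(region)
        for regions in by_chrom.values():
            regions.sort(key=lambda r: r.start)
            for left, right in zip(regions, regions[1:]):
                if right.start < left.end:
                    logger.warning(
                        "trait %s: overlapping regions %s and %s",
                        trait.trait_id, left.region_id, right.region_id,
                    )


def assign_genes(dataset: Sequence[Trait], genome: GenomeIndex) -> list[Trait]:
    """Return traits with each region's gene set filled from the genome index."""
    out: list[Trait] = []
    for trait in dataset:
        regions = [
            replace(region, gene_ids=genome.overlapping(
                region.chrom, region.start, region.end))
            for region in trait.regions
        ]
        out.append(Trait(trait.trait_id, trait.trait_type, regions))
    return out


def apply_filters(
    dataset: Sequence[Trait], config: PipelineConfig
) -> tuple[list[Trait], pd.DataFrame]:
    """Drop oversized regions, then traits with too few regions; log every drop.

    Regions with more than ``region_gene_cap`` genes are removed first; traits
    whose remaining region count is below ``min_regions[trait_type]`` are then
    removed entirely.
    """
    kept: list[Trait] = []
    log: list[dict[str, str]] = []
    for trait in dataset:
        surviving: list[QTLRegion] = []
        for region in trait.regions:
            if len(region.gene_ids) > config.region_gene_cap:
                log.append({
                    "level": "region",
                    "trait_id": trait.trait_id,
                    "item": region.region_id,
                    "reason": (
                        f"{len(region.gene_ids)} genes > cap {config.region_gene_cap}"
                    ),
                })
            else:
                surviving.append(region)
        minimum = config.min_regions[trait.trait_type]
        if len(surviving) < minimum:
            log.append({
                "level": "trait",
                "trait_id": trait.trait_id,
                "item": trait.trait_id,
                "reason": (
                    f"{len(surviving)} regions < min {minimum} for {trait.trait_type}"
                ),
            })
        else:
            kept.append(Trait(trait.trait_id, trait.trait_type, surviving))
    columns = ["level", "trait_id", "item", "reason"]
    return kept, pd.DataFrame(log, columns=columns)


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    if not values:
        return 0.0, 0.0
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return mean, sd


def dataset_summary(dataset: Sequence[Trait]) -> pd.DataFrame:
    """Per-trait-type descriptive statistics, formatted as ``mean (sd)``."""
    rows = []
    for trait_type in TRAIT_TYPES:
        traits = [t for t in dataset if t.trait_type == trait_type]
        regions_per_trait = [t.n_regions for t in traits]
        genes_per_trait = [len(t.gene_ids) for t in traits]
        genes_per_region = [
            len(r.gene_ids) for t in traits for r in t.regions
        ]
        row = {"trait_type": trait_type, "n_traits": len(traits)}
        for label, values in (
            ("regions_per_trait", regions_per_trait),
            ("genes_per_trait", genes_per_trait),
            ("genes_per_region", genes_per_region),
        ):
            mean, sd = _mean_sd(values)
            row[label] = f"{mean:.1f} ({sd:.1f})"
        rows.append(row)
    return pd.DataFrame(rows)


def write_qtl_table(dataset: Sequence[Trait], path: str,
                    *, one_based: bool = False) -> None:
    offset = 1 if one_based else 0
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("trait_id\ttrait_type\tchrom\tstart\tend\n")
        for trait in dataset:
            for region in trait.regions:
                handle.write(
                    f"{trait.trait_id}\t{trait.trait_type}\t{region.chrom}\t"
                    f"{region.start + offset}\t{region.end}\n"
                )
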