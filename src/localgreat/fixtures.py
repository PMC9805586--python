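"""Seeded synthetic-data generator.

Emits every input the pipeline consumes — a genome, a TSS annotation, a
gene-set collection, and region sets — under a single integer seed, so the
statistical behaviour of the enrichment machinery is testable end to end
without downloads. Region midpoints are drawn uniformly over the genome
(the binomial model's null); optionally a fraction of midpoints is planted
inside a chosen term's domain to create a known enrichment signal.

Placement is uniform and independent; no attempt is made to mimic real
genome architecture (gene clustering, GC, assembly gaps).
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike
from pathlib import Path

import numpy as np

from .domains import GeneAnnotation
from .errors import InputError
from .formats import (
    GeneSet,
    GeneSetCollection,
    write_bed,
    write_chrom_sizes,
    write_gene_table,
    write_gmt,
)
from .intervals import Genome, GenomicInterval, IntervalSet, intersect, merge

__all__ = [
    "FixtureConfig",
    "make_genome",
    "make_genes",
    "make_gene_sets",
    "make_regions",
    "write_fixture",
]

# distinct stream keys so each generator draws independently under one seed
_STREAM_GENES = 1
_STREAM_SETS = 2
_STREAM_REGIONS = 3


@dataclass(frozen=True, slots=True)
class FixtureConfig:
    """Study conditions for the synthetic fixtures.

    Defaults give a 2 x 5 Mb genome carrying 200 genes (~50 kb TSS
    spacing), 20 gene sets of 10 genes, and 500 width-50 regions — sized so
    a typical 10-gene term domain covers roughly a tenth of the genome
    under default domain parameters.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 200
    n_terms: int = 20
    genes_per_term: int = 10
    n_regions: int = 500
    region_width: int = 50
    enrichment_fraction: float = 0.0

    def __post_init__(self):
        counts = (
            self.n_chrom,
            self.chrom_length,
            self.n_genes,
            self.n_terms,
            self.genes_per_term,
            self.n_regions,
            self.region_width,
        )
        if min(counts) < 1:
            raise InputError("all fixture counts/sizes must be >= 1")
        if not 0.0 <= self.enrichment_fraction <= 1.0:
            raise InputError("enrichment_fraction must lie in [0, 1]")
        if self.genes_per_term > self.n_genes:
            raise InputError("genes_per_term cannot exceed n_genes")
        if self.region_width > self.chrom_length:
            raise InputError("region_width cannot exceed chrom_length")


def _rng(config: FixtureConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def make_genome(config: FixtureConfig) -> Genome:
    """n_chrom equal-length chromosomes named chr1, chr2, ..."""
    return Genome(
        [(f"chr{i + 1}", config.chrom_length) for i in range(config.n_chrom)]
    )


def make_genes(genome: Genome, config: FixtureConfig) -> list[GeneAnnotation]:
    """TSSs uniform without replacement per chromosome, strands fair coins.

    Genes are spread over chromosomes proportionally to length and named
    g0001, g0002, ... in (chromosome, position) order.
    """
    rng = _rng(config, _STREAM_GENES)
    total = genome.total_size
    chroms = list(genome.items())
    # proportional allocation, remainders to the longest chromosomes first
    raw = [config.n_genes * length / total for _, length in chroms]
    counts = [int(x) for x in raw]
    short = config.n_genes - sum(counts)
    for i in sorted(range(len(chroms)), key=lambda i: raw[i] - counts[i], reverse=True)[:short]:
        counts[i] += 1
    genes: list[GeneAnnotation] = []
    idx = 1
    for (chrom, length), k in zip(chroms, counts):
        if k == 0:
            continue
        if k > length:
            raise InputError(f"cannot place {k} distinct TSSs on {length} bp")
        tss = np.sort(rng.choice(length, size=k, replace=False))
        strands = rng.random(k) < 0.5
        for pos, minus in zip(tss, strands):
            genes.append(
                GeneAnnotation(f"g{idx:04d}", chrom, "-" if minus else "+", int(pos))
            )
            idx += 1
    return genes


def make_gene_sets(genes: list[GeneAnnotation], config: FixtureConfig) -> GeneSetCollection:
    """n_terms sets of genes_per_term members, sampled without replacement."""
    if not genes:
        raise InputError("need at least one gene")
    rng = _rng(config, _STREAM_SETS)
    ids = [g.gene_id for g in genes]
    sets: dict[str, GeneSet] = {}
    for t in range(1, config.n_terms + 1):
        members = sorted(rng.choice(ids, size=config.genes_per_term, replace=False))
        term = f"T{t:03d}"
        sets[term] = GeneSet(term, f"synthetic gene set {t}", tuple(members))
    return GeneSetCollection(sets, source="synthetic")


def _interior(genome: Genome, width: int) -> IntervalSet:
    """Admissible midpoints so that a width-`width` region stays in bounds."""
    half = width // 2
    ivs = []
    for chrom, length in genome.items():
        lo, hi = half, length - width + half + 1
        if hi > lo:
            ivs.append(GenomicInterval(chrom, lo, hi))
    if not ivs:
        raise InputError("region_width leaves no admissible midpoint")
    return IntervalSet(ivs, genome, merged=True, _validated=True)


def _sample_midpoints(universe: IntervalSet, n: int, rng: np.random.Generator) -> list[tuple[str, int]]:
    """n midpoints uniform over the covered bases of a merged universe."""
    ivs = merge(universe).intervals
    widths = np.array([iv.width for iv in ivs], dtype=np.int64)
    cum = np.cumsum(widths)
    draws = rng.integers(0, cum[-1], size=n)
    which = np.searchsorted(cum, draws, side="right")
    out = []
    for d, j in zip(draws, which):
        iv = ivs[j]
        offset = int(d) - (int(cum[j]) - iv.width)
        out.append((iv.chrom, iv.start + offset))
    return out


def make_regions(
    genome: Genome,
    config: FixtureConfig,
    target_domain: IntervalSet | None = None,
) -> IntervalSet:
    """n_regions fixed-width regions with uniform midpoints.

    With a target domain, ``round(enrichment_fraction * n_regions)``
    midpoints are drawn uniformly from the domain's covered bases and the
    rest genome-wide; with no target (or fraction 0) all midpoints are
    uniform over the genome. Regions are named r000001, r000002, ... in
    draw order.
    """
    rng = _rng(config, _STREAM_REGIONS)
    w = config.region_width
    interior = _interior(genome, w)
    n_planted = 0
    if target_domain is not None and config.enrichment_fraction > 0:
        n_planted = round(config.enrichment_fraction * config.n_regions)
    mids: list[tuple[str, int]] = []
    if n_planted:
        dom = intersect(merge(target_domain), interior)
        if dom.is_empty():
            raise InputError("target domain admits no in-bounds midpoint")
        mids.extend(_sample_midpoints(dom, n_planted, rng))
    if config.n_regions - n_planted:
        mids.extend(_sample_midpoints(interior, config.n_regions - n_planted, rng))
    half = w // 2
    ivs = [
        GenomicInterval(chrom, mid - half, mid - half + w, ".", f"r{i + 1:06d}")
        for i, (chrom, mid) in enumerate(mids)
    ]
    return IntervalSet(ivs, genome)


def write_fixture(
    out_dir: str | PathLike,
    config: FixtureConfig,
    target_domain: IntervalSet | None = None,
) -> dict[str, Path]:
    """Write a complete fixture (chrom.sizes, gene table, GMT, regions BED).

    Returns the path of each written file keyed by role. The on-disk files
    round-trip through the package's own readers, so a written fixture is a
    ready-made end-to-end CLI input.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = make_genome(config)
    genes = make_genes(genome, config)
    sets = make_gene_sets(genes, config)
    regions = make_regions(genome, config, target_domain)
    paths = {
        "chrom_sizes": out / "genome.chrom.sizes",
        "genes": out / "genes.tsv",
        "gene_sets": out / "sets.gmt",
        "regions": out / "regions.bed",
    }
    write_chrom_sizes(paths["chrom_sizes"], genome)
    write_gene_table(paths["genes"], genes)
    write_gmt(paths["gene_sets"], sets)
    write_bed(paths["regions"], regions)
    return paths
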