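"""Regulatory-domain construction (basal-plus-extension).

Each gene gets a strand-aware *basal* window around its TSS (default 5 kb
upstream, 1 kb downstream), which is then *extended* in both directions up
to a maximum (default 1 Mb) or until it reaches another gene's basal
domain, whichever comes first. The merged union of the extended domains of
all genes in one gene set is that term's region set; the fraction of the
genome it covers is the binomial success probability ``p``.

The neighbor rule is boundary-based and strand-agnostic: the extension on a
given side stops at the nearest other basal boundary on that side, and is
zero when another gene's basal boundary already lies inside (or at the
shared edge of) this gene's basal interval. The basal interval itself is
never shrunk, even for genes whose basal domain is fully covered by a
neighbor's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .intervals import Genome, GenomicInterval, IntervalSet, merge, total_length

__all__ = [
    "GeneAnnotation",
    "DomainParams",
    "RegulatoryDomain",
    "TermDomain",
    "basal_domain",
    "extend_domains",
    "term_domain",
]


@dataclass(frozen=True, slots=True)
class GeneAnnotation:
    """One gene reduced to a single TSS position (0-based) on a strand."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise InputError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.tss < 0:
            raise InputError(f"gene {self.gene_id!r}: negative TSS {self.tss}")


@dataclass(frozen=True, slots=True)
class DomainParams:
    """Basal-plus-extension parameters, in bases.

    Defaults follow the classic GREAT setting: 5 kb upstream and 1 kb
    downstream of the TSS for the basal domain, extensions capped at 1 Mb.
    """

    basal_upstream: int = 5000
    basal_downstream: int = 1000
    max_extension: int = 1_000_000
    mode: str = "basal_plus_extension"

    def __post_init__(self):
        if min(self.basal_upstream, self.basal_downstream, self.max_extension) < 0:
            raise InputError("domain parameters must be non-negative")
        if self.mode != "basal_plus_extension":
            raise InputError(f"unsupported association mode {self.mode!r}")


@dataclass(frozen=True, slots=True)
class RegulatoryDomain:
    gene_id: str
    basal: GenomicInterval
    extended: GenomicInterval


@dataclass(frozen=True, slots=True)
class TermDomain:
    """Merged region set of one gene set, with its genome fraction ``p``."""

    term_id: str
    domain: IntervalSet
    p: float
    n_genes_matched: int
    n_genes_dropped: int = 0
    empty: bool = field(default=False)


def basal_domain(gene: GeneAnnotation, params: DomainParams, genome: Genome) -> GenomicInterval:
    """Strand-aware basal window around the TSS, clipped to the chromosome."""
    length = genome[gene.chrom]
    if gene.tss >= length:
        raise InputError(
            f"gene {gene.gene_id!r}: TSS {gene.tss} beyond end of {gene.chrom} ({length} bp)"
        )
    if gene.strand == "+":
        start = gene.tss - params.basal_upstream
        end = gene.tss + params.basal_downstream
    else:
        start = gene.tss - params.basal_downstream
        end = gene.tss + params.basal_upstream
    start = max(start, 0)
    end = min(end, length)
    if end <= start:  # zero-size basal possible only with 0/0 params at an edge
        end = min(start + 1, length)
        start = end - 1
    return GenomicInterval(gene.chrom, start, end, gene.strand, gene.gene_id)


def extend_domains(
    genes: list[GeneAnnotation], params: DomainParams, genome: Genome
) -> list[RegulatoryDomain]:
    """Build the extended regulatory domain of every gene.

    Per chromosome and per side, a gene's extension runs from its basal
    boundary to the nearest other basal boundary on that side, capped at
    ``max_extension`` and the chromosome ends. Returned in input-independent
    deterministic order (chromosome, TSS, gene_id).
    """
    if not genes:
        raise InputError("need at least one gene to build domains")
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise InputError(f"duplicate gene_id: {g.gene_id!r}")
        seen.add(g.gene_id)

    order = {c: i for i, c in enumerate(genome)}
    genes = sorted(genes, key=lambda g: (order[g.chrom], g.tss, g.gene_id))

    out: list[RegulatoryDomain] = []
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    for chrom, chrom_genes in by_chrom.items():
        length = genome[chrom]
        basals = [basal_domain(g, params, genome) for g in chrom_genes]
        starts = np.array([b.start for b in basals], dtype=np.int64)
        ends = np.array([b.end for b in basals], dtype=np.int64)
        n = len(basals)
        for i, (g, b) in enumerate(zip(chrom_genes, basals)):
            others = np.arange(n) != i
            os, oe = starts[others], ends[others]
            # left: neighbors whose basal starts at or before ours limit the
            # extension at min(their end, our start)
            lmask = os <= b.start
            left_limit = 0 if not lmask.any() else int(np.minimum(oe[lmask], b.start).max())
            ext_start = max(b.start - params.max_extension, left_limit, 0)
            # right: mirror image
            rmask = oe >= b.end
            right_limit = length if not rmask.any() else int(np.maximum(os[rmask], b.end).min())
            ext_end = min(b.end + params.max_extension, right_limit, length)
            ext_start = min(ext_start, b.start)  # never shrink the basal
            ext_end = max(ext_end, b.end)
            out.append(
                RegulatoryDomain(
                    g.gene_id,
                    b,
                    GenomicInterval(chrom, ext_start, ext_end, g.strand, g.gene_id),
                )
            )
    return out


def term_domain(
    term_gene_ids: set[str] | frozenset[str],
    domains: list[RegulatoryDomain],
    genome: Genome,
    term_id: str = "",
) -> TermDomain:
    """Merged union of the extended domains of a gene set's members.

    Members absent from the annotation are tallied in ``n_genes_dropped``;
    a term with no annotated member yields an empty, flagged domain with
    ``p = 0``.
    """
    by_id = {d.gene_id: d for d in domains}
    matched = [by_id[g] for g in sorted(term_gene_ids) if g in by_id]
    dropped = len(term_gene_ids) - len(matched)
    if not matched:
        return TermDomain(term_id, IntervalSet.empty(genome), 0.0, 0, dropped, empty=True)
    dom = merge(IntervalSet([d.extended for d in matched], genome))
    p = total_length(dom) / genome.total_size
    return TermDomain(term_id, dom, p, len(matched), dropped)
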