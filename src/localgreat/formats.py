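"""Readers and writers for the external formats.

BED (3-6 columns), UCSC chrom.sizes, GMT gene-set collections, a
tab-delimited gene table (gene_id, chrom, strand, tss; 0-based), and a
minimal GTF reader that extracts one TSS per gene. GTF coordinates are
1-based closed and are converted to the package's 0-based half-open
convention on read.

Chromosome-name matching is exact; no chr1/1 aliasing is attempted, but a
two-column rename map can be applied to incoming records as an escape
hatch. Records on chromosomes absent from the genome are skipped with a
counted warning by default (policy="skip") or rejected (policy="error").
Readers accept an optional ``collections.Counter`` tally to which they add
machine-readable warning counts.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass
from os import PathLike
from typing import Iterable

from .domains import GeneAnnotation
from .errors import AnnotationMismatchError, FormatError, InputError
from .intervals import Genome, GenomicInterval, IntervalSet

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_gmt",
    "write_gmt",
    "read_gene_table",
    "write_gene_table",
    "read_gtf_genes",
    "read_rename_map",
]

log = logging.getLogger(__name__)

_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, slots=True)
class GeneSet:
    term_id: str
    description: str
    members: tuple[str, ...]


@dataclass(frozen=True)
class GeneSetCollection:
    """A GMT-shaped collection: unique term ids, non-empty member lists."""

    sets: dict[str, GeneSet]
    source: str = ""

    def __post_init__(self):
        for term_id, gs in self.sets.items():
            if not gs.members:
                raise InputError(f"gene set {term_id!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, term_id: str) -> GeneSet:
        return self.sets[term_id]


def _open_lines(path: str | PathLike):
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            yield lineno, raw.rstrip("\n").rstrip("\r")


def read_rename_map(path: str | PathLike) -> dict[str, str]:
    """Two tab-separated columns: name-in-file -> canonical genome name."""
    out: dict[str, str] = {}
    for lineno, line in _open_lines(path):
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: rename map needs exactly 2 columns")
        out[parts[0]] = parts[1]
    return out


def read_chrom_sizes(path: str | PathLike) -> Genome:
    """UCSC chrom.sizes: two tab-separated columns (name, length)."""
    sizes: list[tuple[str, int]] = []
    for lineno, line in _open_lines(path):
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
        try:
            length = int(parts[1])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: length {parts[1]!r} is not an integer") from None
        sizes.append((parts[0], length))
    if not sizes:
        raise FormatError(f"{path}: no chromosomes found")
    return Genome(sizes)


def write_chrom_sizes(path: str | PathLike, genome: Genome) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for name, length in genome.items():
            fh.write(f"{name}\t{length}\n")


def read_bed(
    path: str | PathLike,
    genome: Genome,
    unknown_chrom: str = "skip",
    rename: dict[str, str] | None = None,
    tally: Counter | None = None,
) -> IntervalSet:
    """Read a 3-6 column BED file into an (unmerged) IntervalSet.

    track/browser/# lines are ignored. ``unknown_chrom`` is "skip"
    (default; skipped records are counted under ``bed_unknown_chrom``) or
    "error".
    """
    if unknown_chrom not in ("skip", "error"):
        raise InputError(f"unknown_chrom must be 'skip' or 'error', got {unknown_chrom!r}")
    tally = tally if tally is not None else Counter()
    ivs: list[GenomicInterval] = []
    for lineno, line in _open_lines(path):
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: BED needs at least 3 columns")
        chrom = rename.get(parts[0], parts[0]) if rename else parts[0]
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
        if chrom not in genome:
            if unknown_chrom == "error":
                raise AnnotationMismatchError(
                    f"{path}:{lineno}: chromosome {chrom!r} absent from genome"
                )
            tally["bed_unknown_chrom"] += 1
            continue
        name = parts[3] if len(parts) > 3 and parts[3] not in ("", ".") else None
        strand = parts[5] if len(parts) > 5 and parts[5] in _STRANDS else "."
        if start < 0 or end <= start or end > genome[chrom]:
            raise InputError(
                f"{path}:{lineno}: interval {chrom}:{start}-{end} out of bounds "
                f"for {chrom} ({genome[chrom]} bp)"
            )
        ivs.append(GenomicInterval(chrom, start, end, strand, name))
    if tally["bed_unknown_chrom"]:
        log.warning(
            "%s: skipped %d record(s) on chromosomes absent from the genome",
            path,
            tally["bed_unknown_chrom"],
        )
    return IntervalSet(ivs, genome)


def write_bed(path: str | PathLike, regions: IntervalSet) -> None:
    """Write sorted BED3+name (name '.' when absent)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for iv in regions:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\n")


def read_gmt(path: str | PathLike, tally: Counter | None = None) -> GeneSetCollection:
    """GMT: per line, term id, description, then member genes.

    Duplicate members within a set are deduplicated (counted under
    ``gmt_duplicate_member``); sets left empty are dropped (counted under
    ``gmt_empty_set``).
    """
    tally = tally if tally is not None else Counter()
    sets: dict[str, GeneSet] = {}
    for lineno, line in _open_lines(path):
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT needs >= 3 tab-separated fields "
                f"(name, description, members...), got {len(parts)}"
            )
        term_id, desc = parts[0], parts[1]
        if term_id in sets:
            raise FormatError(f"{path}:{lineno}: duplicate gene set id {term_id!r}")
        members: list[str] = []
        seen: set[str] = set()
        for m in parts[2:]:
            if not m:
                continue
            if m in seen:
                tally["gmt_duplicate_member"] += 1
                continue
            seen.add(m)
            members.append(m)
        if not members:
            tally["gmt_empty_set"] += 1
            continue
        sets[term_id] = GeneSet(term_id, desc, tuple(members))
    if tally["gmt_duplicate_member"] or tally["gmt_empty_set"]:
        log.warning(
            "%s: %d duplicate member(s) deduplicated, %d empty set(s) dropped",
            path,
            tally["gmt_duplicate_member"],
            tally["gmt_empty_set"],
        )
    if not sets:
        raise FormatError(f"{path}: no usable gene sets")
    return GeneSetCollection(sets, source=str(path))


def write_gmt(path: str | PathLike, collection: GeneSetCollection) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for gs in collection:
            fh.write("\t".join([gs.term_id, gs.description, *gs.members]) + "\n")


def _check_gene(
    gene_id: str,
    chrom: str,
    strand: str,
    tss: int,
    genome: Genome,
    ctx: str,
    unknown_chrom: str,
    tally: Counter,
) -> GeneAnnotation | None:
    if chrom not in genome:
        if unknown_chrom == "error":
            raise AnnotationMismatchError(f"{ctx}: chromosome {chrom!r} absent from genome")
        tally["gene_unknown_chrom"] += 1
        return None
    if not 0 <= tss < genome[chrom]:
        raise InputError(f"{ctx}: TSS {tss} out of bounds for {chrom} ({genome[chrom]} bp)")
    return GeneAnnotation(gene_id, chrom, strand, tss)


def read_gene_table(
    path: str | PathLike,
    genome: Genome,
    unknown_chrom: str = "skip",
    rename: dict[str, str] | None = None,
    tally: Counter | None = None,
) -> list[GeneAnnotation]:
    """Tab-delimited gene_id, chrom, strand, tss (0-based); optional header."""
    tally = tally if tally is not None else Counter()
    genes: list[GeneAnnotation] = []
    for lineno, line in _open_lines(path):
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise FormatError(f"{path}:{lineno}: gene table needs 4 columns")
        if lineno == 1 and parts[0] == "gene_id":
            continue  # header
        chrom = rename.get(parts[1], parts[1]) if rename else parts[1]
        try:
            tss = int(parts[3])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: TSS {parts[3]!r} is not an integer") from None
        if parts[2] not in ("+", "-"):
            raise FormatError(f"{path}:{lineno}: strand must be '+' or '-', got {parts[2]!r}")
        g = _check_gene(
            parts[0], chrom, parts[2], tss, genome, f"{path}:{lineno}", unknown_chrom, tally
        )
        if g is not None:
            genes.append(g)
    if not genes:
        raise InputError(f"{path}: no usable genes")
    _reject_duplicates(genes, path)
    return genes


def write_gene_table(path: str | PathLike, genes: Iterable[GeneAnnotation]) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\n")


_GTF_GENE_ID = re.compile(r'gene_id\s+"([^"]+)"')


def read_gtf_genes(
    path: str | PathLike,
    genome: Genome,
    feature: str = "gene",
    unknown_chrom: str = "skip",
    rename: dict[str, str] | None = None,
    tally: Counter | None = None,
) -> list[GeneAnnotation]:
    """Extract one TSS per gene from a GTF file.

    Only lines whose feature column matches ``feature`` are used (set it to
    "transcript" for transcript-level annotations). The TSS is the 0-based
    position of the 5' end: GTF start-1 on '+', GTF end-1 on '-'. When a
    gene has several matching records (multiple transcripts), the 5'-most
    TSS on the gene's strand is kept; the reduction is counted under
    ``gtf_multi_tss``.
    """
    tally = tally if tally is not None else Counter()
    best: dict[str, GeneAnnotation] = {}
    for lineno, line in _open_lines(path):
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 9:
            raise FormatError(f"{path}:{lineno}: GTF needs 9 tab-separated columns")
        if parts[2] != feature:
            continue
        chrom = rename.get(parts[0], parts[0]) if rename else parts[0]
        strand = parts[6]
        if strand not in ("+", "-"):
            tally["gtf_unstranded"] += 1
            continue
        try:
            start1, end1 = int(parts[3]), int(parts[4])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
        if start1 < 1 or end1 < start1:
            raise InputError(f"{path}:{lineno}: invalid 1-based range {start1}-{end1}")
        m = _GTF_GENE_ID.search(parts[8])
        if not m:
            raise FormatError(f"{path}:{lineno}: no gene_id attribute found")
        gene_id = m.group(1)
        tss = start1 - 1 if strand == "+" else end1 - 1
        g = _check_gene(
            gene_id, chrom, strand, tss, genome, f"{path}:{lineno}", unknown_chrom, tally
        )
        if g is None:
            continue
        prev = best.get(gene_id)
        if prev is None:
            best[gene_id] = g
        else:
            tally["gtf_multi_tss"] += 1
            if prev.strand != g.strand or prev.chrom != g.chrom:
                raise InputError(
                    f"{path}:{lineno}: gene {gene_id!r} appears on conflicting "
                    "chromosomes/strands"
                )
            # 5'-most: smallest coordinate on '+', largest on '-'
            if (g.strand == "+" and g.tss < prev.tss) or (g.strand == "-" and g.tss > prev.tss):
                best[gene_id] = g
    if not best:
        raise InputError(f"{path}: no usable {feature!r} records")
    return list(best.values())


def _reject_duplicates(genes: list[GeneAnnotation], path) -> None:
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise InputError(f"{path}: duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
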