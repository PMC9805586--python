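"""Exact genomic interval arithmetic.

All coordinates are 0-based half-open (BED convention): an interval
``[start, end)`` covers the bases ``start .. end-1``. Strand is carried on
intervals but ignored by every operation here; it only matters upstream,
when transcription start sites are derived from an annotation.

The covered-base semantics of :func:`merge`, :func:`intersect` and
:func:`subtract` are the ground truth the rest of the package builds on:
the per-term genome fraction ``p`` and its background-restricted variant
``p2`` are ratios of :func:`total_length` values, and enrichment trials are
counted with :func:`count_hits`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np

from .errors import AnnotationMismatchError, InputError

__all__ = [
    "Genome",
    "GenomicInterval",
    "IntervalSet",
    "merge",
    "intersect",
    "subtract",
    "total_length",
    "count_hits",
]

HIT_MODES = ("midpoint", "any_overlap")


class Genome:
    """Ordered chromosome name -> length (bases) map.

    The chromosome order given at construction is preserved and defines the
    canonical sort order for interval sets and all written output.
    """

    __slots__ = ("_sizes",)

    def __init__(self, sizes: Mapping[str, int] | Iterable[tuple[str, int]]):
        items = list(sizes.items()) if isinstance(sizes, Mapping) else list(sizes)
        if not items:
            raise InputError("a genome needs at least one chromosome")
        seen: dict[str, int] = {}
        for name, length in items:
            if name in seen:
                raise InputError(f"duplicate chromosome name: {name!r}")
            length = int(length)
            if length <= 0:
                raise InputError(f"chromosome {name!r} has non-positive length {length}")
            seen[str(name)] = length
        self._sizes = seen

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(self._sizes)

    @property
    def total_size(self) -> int:
        return sum(self._sizes.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __getitem__(self, chrom: str) -> int:
        try:
            return self._sizes[chrom]
        except KeyError:
            raise AnnotationMismatchError(f"unknown chromosome: {chrom!r}") from None

    def __len__(self) -> int:
        return len(self._sizes)

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def items(self):
        return self._sizes.items()

    def __eq__(self, other) -> bool:
        return isinstance(other, Genome) and self._sizes == other._sizes

    def __repr__(self) -> str:
        return f"Genome({len(self)} chromosomes, {self.total_size} bp)"

    def chrom_rank(self, chrom: str) -> int:
        """Position of ``chrom`` in the canonical ordering."""
        for i, name in enumerate(self._sizes):
            if name == chrom:
                return i
        raise AnnotationMismatchError(f"unknown chromosome: {chrom!r}")

    def whole_genome(self) -> "IntervalSet":
        """One interval per chromosome, covering every base."""
        ivs = [GenomicInterval(c, 0, l) for c, l in self._sizes.items()]
        return IntervalSet(ivs, self, merged=True, _validated=True)


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on one chromosome.

    ``strand`` is '+', '-' or '.' (unstranded); ``name`` is an optional
    label carried through intersect/subtract fragments.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise InputError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise InputError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        # floor((start+end)/2); deterministic for even widths
        return (self.start + self.end) // 2

    def coords(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


class IntervalSet:
    """A genome-validated collection of intervals, sorted per chromosome.

    ``merged`` records whether the intervals are known to be pairwise
    disjoint and non-adjacent (the output of :func:`merge`). Sets keep one
    entry per input interval: duplicates and overlaps are legal in an
    unmerged set, because each input region is one Bernoulli trial for the
    enrichment test.
    """

    __slots__ = ("genome", "intervals", "merged")

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        genome: Genome,
        merged: bool = False,
        _validated: bool = False,
    ):
        ivs = list(intervals)
        if not _validated:
            for iv in ivs:
                if iv.chrom not in genome:
                    raise AnnotationMismatchError(
                        f"interval {iv} lies on a chromosome absent from the genome: "
                        f"{iv.chrom!r}"
                    )
                if iv.end > genome[iv.chrom]:
                    raise InputError(
                        f"interval {iv} extends past the end of {iv.chrom} "
                        f"({genome[iv.chrom]} bp)"
                    )
            order = {c: i for i, c in enumerate(genome)}
            ivs.sort(key=lambda iv: (order[iv.chrom], iv.start, iv.end, iv.name or ""))
        self.genome = genome
        self.intervals = tuple(ivs)
        self.merged = bool(merged)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, IntervalSet)
            and self.genome == other.genome
            and self.intervals == other.intervals
        )

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals, merged={self.merged})"

    def is_empty(self) -> bool:
        return not self.intervals

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def arrays_by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) int64 arrays, in set order."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, ivs in self.by_chrom().items():
            out[chrom] = (
                np.fromiter((iv.start for iv in ivs), dtype=np.int64, count=len(ivs)),
                np.fromiter((iv.end for iv in ivs), dtype=np.int64, count=len(ivs)),
            )
        return out

    @classmethod
    def empty(cls, genome: Genome) -> "IntervalSet":
        return cls((), genome, merged=True, _validated=True)


def merge(s: IntervalSet) -> IntervalSet:
    """Coalesce overlapping and book-ended intervals.

    The returned set covers exactly the same bases as the input; adjacent
    intervals (``prev.end == next.start``) are joined, strand and names are
    dropped. Idempotent.
    """
    if s.merged:
        return s
    out: list[GenomicInterval] = []
    for chrom, ivs in s.by_chrom().items():
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or book-ended
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return IntervalSet(out, s.genome, merged=True, _validated=True)


def _check_same_genome(a: IntervalSet, b: IntervalSet) -> None:
    if a.genome != b.genome:
        raise InputError("interval sets belong to different genomes")


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Per-interval intersection of ``a`` with the merged cover of ``b``.

    Each interval of ``a`` is clipped against ``b``; fragments inherit the
    name (and strand) of the ``a``-interval they derive from. Covered bases
    of the result equal covered(a) AND covered(b).
    """
    _check_same_genome(a, b)
    bm = merge(b).arrays_by_chrom()
    out: list[GenomicInterval] = []
    for iv in a:
        arrs = bm.get(iv.chrom)
        if arrs is None:
            continue
        starts, ends = arrs
        # first b-interval that may overlap: end > iv.start
        i = int(np.searchsorted(ends, iv.start, side="right"))
        while i < len(starts) and starts[i] < iv.end:
            s = max(iv.start, int(starts[i]))
            e = min(iv.end, int(ends[i]))
            if s < e:
                out.append(GenomicInterval(iv.chrom, s, e, iv.strand, iv.name))
            i += 1
    return IntervalSet(out, a.genome, merged=a.merged, _validated=False)


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Remove the bases covered by ``b`` from each interval of ``a``.

    Fragments inherit name and strand from their source interval; covered
    bases of the result equal covered(a) AND NOT covered(b).
    """
    _check_same_genome(a, b)
    bm = merge(b).arrays_by_chrom()
    out: list[GenomicInterval] = []
    for iv in a:
        arrs = bm.get(iv.chrom)
        if arrs is None:
            out.append(iv)
            continue
        starts, ends = arrs
        cursor = iv.start
        i = int(np.searchsorted(ends, iv.start, side="right"))
        while i < len(starts) and starts[i] < iv.end:
            s, e = int(starts[i]), int(ends[i])
            if s > cursor:
                out.append(GenomicInterval(iv.chrom, cursor, s, iv.strand, iv.name))
            cursor = max(cursor, e)
            i += 1
        if cursor < iv.end:
            out.append(GenomicInterval(iv.chrom, cursor, iv.end, iv.strand, iv.name))
    return IntervalSet(out, a.genome, merged=a.merged, _validated=False)


def total_length(s: IntervalSet) -> int:
    """Number of distinct bases covered by the set."""
    m = s if s.merged else merge(s) if len(s) else s
    return sum(iv.width for iv in m)


def count_hits(regions: IntervalSet, domain: IntervalSet, hit_mode: str = "midpoint") -> int:
    """Number of regions that "fall in" the domain.

    midpoint mode: a region hits iff ``floor((start+end)/2)`` is a covered
    base of the domain. any_overlap mode: a region hits iff it shares at
    least one base with the domain. Each region is counted at most once;
    regions are NOT merged with each other first (one region = one trial).
    """
    if hit_mode not in HIT_MODES:
        raise InputError(f"unknown hit_mode {hit_mode!r}; expected one of {HIT_MODES}")
    dm = (domain if domain.merged else merge(domain)).arrays_by_chrom()
    hits = 0
    for chrom, ivs in regions.by_chrom().items():
        arrs = dm.get(chrom)
        if arrs is None:
            continue
        starts, ends = arrs
        if hit_mode == "midpoint":
            mids = np.fromiter((iv.midpoint for iv in ivs), dtype=np.int64, count=len(ivs))
            idx = np.searchsorted(starts, mids, side="right") - 1
            ok = idx >= 0
            ok[ok] = ends[idx[ok]] > mids[ok]
            hits += int(ok.sum())
        else:
            rs = np.fromiter((iv.start for iv in ivs), dtype=np.int64, count=len(ivs))
            re_ = np.fromiter((iv.end for iv in ivs), dtype=np.int64, count=len(ivs))
            # first domain interval with end > region.start
            idx = np.searchsorted(ends, rs, side="right")
            ok = idx < len(starts)
            ok[ok] = starts[idx[ok]] < re_[ok]
            hits += int(ok.sum())
    return hits
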