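"""Region-gene association tables.

For each input region, report the genes whose regulatory domains it falls
in, with the signed distance from the region midpoint to the TSS. The sign
is strand-relative: negative means the midpoint lies 5' (upstream) of the
TSS, positive 3' (downstream), so a distance of -1 kb reads "1 kb upstream"
regardless of strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .domains import RegulatoryDomain
from .errors import InputError
from .intervals import HIT_MODES, GenomicInterval, IntervalSet

__all__ = [
    "AssociationRecord",
    "AssociationTable",
    "associate",
    "distance_summary",
    "DEFAULT_DISTANCE_EDGES",
]

# bin edges (bases, signed); bins are half-open [low, high)
DEFAULT_DISTANCE_EDGES = (-500_000, -50_000, -5_000, 0, 5_000, 50_000, 500_000)


@dataclass(frozen=True, slots=True)
class AssociationRecord:
    region: GenomicInterval
    gene_id: str
    signed_distance: int


@dataclass(frozen=True)
class AssociationTable:
    records: tuple[AssociationRecord, ...]
    n_regions_unassociated: int

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_chrom": [r.region.chrom for r in self.records],
                "region_start": [r.region.start for r in self.records],
                "region_end": [r.region.end for r in self.records],
                "gene_id": [r.gene_id for r in self.records],
                "signed_distance": [r.signed_distance for r in self.records],
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def associate(
    regions: IntervalSet,
    domains: Sequence[RegulatoryDomain],
    genes_tss: dict[str, int],
    hit_mode: str = "midpoint",
) -> AssociationTable:
    """One record per (region, gene) pair whose extended domain it hits.

    ``genes_tss`` maps gene_id -> TSS (0-based), as carried by the
    annotation the domains were built from. A region overlapping several
    (possibly overlapping) domains yields several records; regions hitting
    no domain are tallied.
    """
    if hit_mode not in HIT_MODES:
        raise InputError(f"unknown hit_mode {hit_mode!r}; expected one of {HIT_MODES}")
    # per-chromosome arrays of domain bounds, kept per-gene (not merged)
    by_chrom: dict[str, list[RegulatoryDomain]] = {}
    for d in domains:
        by_chrom.setdefault(d.extended.chrom, []).append(d)
    arrays = {}
    for chrom, ds in by_chrom.items():
        ds.sort(key=lambda d: (d.extended.start, d.extended.end, d.gene_id))
        arrays[chrom] = (
            np.array([d.extended.start for d in ds], dtype=np.int64),
            np.array([d.extended.end for d in ds], dtype=np.int64),
            ds,
        )

    records: list[AssociationRecord] = []
    n_unassociated = 0
    for iv in regions:
        entry = arrays.get(iv.chrom)
        hit_any = False
        if entry is not None:
            starts, ends, ds = entry
            mid = iv.midpoint
            if hit_mode == "midpoint":
                cand = (starts <= mid) & (ends > mid)
            else:
                cand = (starts < iv.end) & (ends > iv.start)
            for j in np.flatnonzero(cand):
                d = ds[j]
                tss = genes_tss[d.gene_id]
                dist = mid - tss if d.basal.strand == "+" else tss - mid
                records.append(AssociationRecord(iv, d.gene_id, int(dist)))
                hit_any = True
        if not hit_any:
            n_unassociated += 1
    return AssociationTable(tuple(records), n_unassociated)


def distance_summary(
    table: AssociationTable | Sequence[AssociationRecord],
    edges: Sequence[int] = DEFAULT_DISTANCE_EDGES,
) -> pd.DataFrame:
    """Histogram of signed midpoint-to-TSS distances.

    Bins are half-open [low, high) between consecutive edges, with open
    bins below the first and at/above the last edge. Counts sum to the
    number of records.
    """
    records = list(table.records if isinstance(table, AssociationTable) else table)
    edges = list(edges)
    if edges != sorted(edges) or len(set(edges)) != len(edges):
        raise InputError("distance bin edges must be strictly increasing")
    dists = np.array([r.signed_distance for r in records], dtype=np.int64)
    bounds = [-np.inf, *edges, np.inf]
    labels, counts = [], []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        labels.append(f"{_fmt(lo)}..{_fmt(hi)}")
        counts.append(int(((dists >= lo) & (dists < hi)).sum()) if len(dists) else 0)
    return pd.DataFrame(
        {"bin": labels, "low": bounds[:-1], "high": bounds[1:], "count": counts}
    )


def _fmt(x: float) -> str:
    if np.isinf(x):
        return "-inf" if x < 0 else "+inf"
    n = int(x)
    if n != 0 and n % 1000 == 0:
        return f"{n // 1000}k"
    return str(n)
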