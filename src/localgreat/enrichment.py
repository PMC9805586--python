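"""Enrichment statistics: binomial model, background restriction, and the
classic hypergeometric background test.

The binomial model: under the null that input regions are placed uniformly
on the genome, the number of the N input regions falling into a term's
merged regulatory domain (genome fraction p) is X ~ B(p, N); the
enrichment P-value is the upper tail Pr(X >= n).

With a background (a pre-selected universe U of regions) or an exclude set
(U = genome minus the excluded regions), the same model is applied to the
restriction: p2 is the fraction of U covered by the domain, N2 counts the
input regions falling in U, n2 those falling in the restricted domain, and
X2 ~ B(p2, N2).

The hypergeometric variant requires the foreground regions to be an exact
subset of the background regions: with N_bg background regions of which
n_bg fall in the domain, and N_fg foreground regions of which n_fg fall in
the domain, X_fg ~ Hyper(N_bg, n_bg, N_fg) and P = Pr(X_fg >= n_fg). When
background regions are disjoint and equal-width, the background-restricted
binomial success probability reduces to p2 = n_bg/N_bg and the two tests
agree closely; the binomial route stays valid for unequal widths and for
foregrounds that are not literal subsets, which is why it is the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .domains import TermDomain
from .errors import ConsistencyError, InputError, SubsetViolationError
from .intervals import (
    Genome,
    IntervalSet,
    count_hits,
    intersect,
    merge,
    subtract,
    total_length,
)

__all__ = [
    "BackgroundSpec",
    "EnrichmentRow",
    "binomial_tail",
    "hypergeometric_tail",
    "adjust_bh",
    "run_great",
    "run_great_hypergeometric",
    "attach_hypergeometric",
]

_TINY = 5e-324  # smallest positive float; keeps P-values in (0, 1]


@dataclass(frozen=True, slots=True)
class BackgroundSpec:
    """Universe restriction: none, an explicit background, or an exclude set."""

    kind: str  # "none" | "background" | "exclude"
    intervals: IntervalSet | None = None

    def __post_init__(self):
        if self.kind not in ("none", "background", "exclude"):
            raise InputError(f"unknown background kind {self.kind!r}")
        if self.kind == "background" and (self.intervals is None or self.intervals.is_empty()):
            raise InputError("kind='background' requires non-empty background intervals")

    @classmethod
    def none(cls) -> "BackgroundSpec":
        return cls("none")

    @classmethod
    def background(cls, intervals: IntervalSet) -> "BackgroundSpec":
        return cls("background", intervals)

    @classmethod
    def exclude(cls, intervals: IntervalSet) -> "BackgroundSpec":
        return cls("exclude", intervals)


@dataclass(frozen=True, slots=True)
class EnrichmentRow:
    """Per-term enrichment statistics.

    ``p_domain``/``n_trials``/``n_hits`` are (p, N, n) for an unrestricted
    run and (p2, N2, n2) under a background or exclude restriction.
    ``fold_enrichment`` is NaN (flagged) when the expectation is zero. The
    hypergeometric fields are populated only by the hypergeometric test.
    """

    term_id: str
    n_genes_matched: int
    p_domain: float
    n_trials: int
    n_hits: int
    expected: float
    fold_enrichment: float
    p_binomial: float | None
    p_adjusted: float
    p_hypergeometric: float | None = None
    n_background: int | None = None  # N_bg
    n_foreground: int | None = None  # N_fg
    hits_background: int | None = None  # n_bg
    hits_foreground: int | None = None  # n_fg


def binomial_tail(n_hits: int, n_trials: int, p_domain: float) -> float:
    """Exact upper tail Pr(X >= n_hits) for X ~ B(p_domain, n_trials)."""
    if not 0.0 <= p_domain <= 1.0:
        raise InputError(f"p_domain must lie in [0, 1], got {p_domain}")
    if n_hits < 0 or n_trials < 0 or n_hits > n_trials:
        raise InputError(f"need 0 <= n_hits <= n_trials, got n_hits={n_hits}, n_trials={n_trials}")
    if n_hits == 0:
        return 1.0
    p = float(stats.binom.sf(n_hits - 1, n_trials, p_domain))
    return min(1.0, max(p, _TINY))


def hypergeometric_tail(n_bg_total: int, n_fg_total: int, hits_bg: int, hits_fg: int) -> float:
    """Exact upper tail Pr(X >= hits_fg), X ~ Hyper(N_bg, n_bg, N_fg).

    Population of ``n_bg_total`` background regions, ``hits_bg`` of them in
    the domain; ``n_fg_total`` foreground regions drawn without replacement.
    """
    if n_fg_total > n_bg_total:
        raise InputError("foreground count exceeds background count")
    if hits_bg > n_bg_total:
        raise InputError("background hits exceed background count")
    if hits_fg > min(n_fg_total, hits_bg):
        raise InputError(
            f"foreground hits ({hits_fg}) exceed min(N_fg={n_fg_total}, n_bg={hits_bg})"
        )
    if min(n_bg_total, n_fg_total, hits_bg, hits_fg) < 0:
        raise InputError("hypergeometric counts must be non-negative")
    if hits_fg == 0:
        return 1.0
    p = float(stats.hypergeom.sf(hits_fg - 1, n_bg_total, hits_bg, n_fg_total))
    return min(1.0, max(p, _TINY))


def adjust_bh(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    if len(p_values) == 0:
        return []
    return [float(q) for q in multipletests(list(p_values), method="fdr_bh")[1]]


def _effective_universe(genome: Genome, background: BackgroundSpec) -> IntervalSet | None:
    """Merged universe U, or None when the run is unrestricted."""
    if background.kind == "none":
        return None
    if background.kind == "background":
        return merge(background.intervals)
    # exclude: empty exclude set is the identity (no restriction)
    if background.intervals is None or background.intervals.is_empty():
        return None
    return subtract(genome.whole_genome(), background.intervals)


def run_great(
    regions: IntervalSet,
    terms: Iterable[TermDomain],
    genome: Genome,
    background: BackgroundSpec | None = None,
    hit_mode: str = "midpoint",
) -> list[EnrichmentRow]:
    """Binomial enrichment of the input regions against every term domain.

    Returns one row per term, sorted by raw binomial P-value (ties broken
    by term_id); BH-adjusted values are computed across the whole
    collection. Trials are whole input regions throughout: under a
    restriction only the domains are clipped, while N2 and n2 count
    original regions falling in the universe / restricted domain.
    """
    if regions.is_empty():
        raise InputError("input region set is empty")
    background = background or BackgroundSpec.none()
    universe = _effective_universe(genome, background)

    if universe is None:
        n_trials = len(regions)
        u_len = genome.total_size
    else:
        u_len = total_length(universe)
        if u_len == 0:
            raise InputError("the effective universe covers zero bases")
        n_trials = count_hits(regions, universe, hit_mode)
        if n_trials == 0:
            raise InputError(
                "no input region falls in the background/universe; "
                "the background does not cover the input regions"
            )

    rows: list[EnrichmentRow] = []
    for term in terms:
        dom = term.domain if universe is None else intersect(term.domain, universe)
        p_dom = (total_length(dom) / u_len) if u_len else 0.0
        n = count_hits(regions, dom, hit_mode) if not dom.is_empty() else 0
        if p_dom == 0.0 and n > 0:
            raise ConsistencyError(
                f"term {term.term_id!r}: {n} hits in a zero-measure domain"
            )
        expected = n_trials * p_dom
        fold = (n / expected) if expected > 0 else math.nan
        rows.append(
            EnrichmentRow(
                term_id=term.term_id,
                n_genes_matched=term.n_genes_matched,
                p_domain=p_dom,
                n_trials=n_trials,
                n_hits=n,
                expected=expected,
                fold_enrichment=fold,
                p_binomial=binomial_tail(n, n_trials, p_dom),
                p_adjusted=math.nan,
            )
        )
    adj = adjust_bh([r.p_binomial for r in rows])
    rows = [replace(r, p_adjusted=max(q, r.p_binomial)) for r, q in zip(rows, adj)]
    rows.sort(key=lambda r: (r.p_binomial, r.term_id))
    return rows


def run_great_hypergeometric(
    fg_regions: IntervalSet,
    bg_regions: IntervalSet,
    terms: Iterable[TermDomain],
    genome: Genome,
    hit_mode: str = "midpoint",
) -> list[EnrichmentRow]:
    """Classic background test: foreground must be a subset of background.

    The subset requirement is checked by exact (chrom, start, end)
    coordinate identity (with multiplicity). Rows are sorted by the
    hypergeometric P-value; ``p_binomial`` is None and ``p_adjusted`` is BH
    over the hypergeometric P-values.
    """
    if fg_regions.is_empty():
        raise InputError("foreground region set is empty")
    from collections import Counter

    bg_counts = Counter(iv.coords() for iv in bg_regions)
    missing = []
    fg_counts = Counter(iv.coords() for iv in fg_regions)
    for coords, k in fg_counts.items():
        if bg_counts.get(coords, 0) < k:
            missing.append(coords)
    if missing:
        shown = ", ".join(f"{c}:{s}-{e}" for c, s, e in sorted(missing)[:10])
        raise SubsetViolationError(
            f"{len(missing)} foreground region(s) absent from the background: {shown}"
        )

    n_bg_total = len(bg_regions)
    n_fg_total = len(fg_regions)
    rows: list[EnrichmentRow] = []
    for term in terms:
        hits_bg = count_hits(bg_regions, term.domain, hit_mode)
        hits_fg = count_hits(fg_regions, term.domain, hit_mode)
        p_draw = hits_bg / n_bg_total
        expected = n_fg_total * p_draw
        fold = (hits_fg / expected) if expected > 0 else math.nan
        rows.append(
            EnrichmentRow(
                term_id=term.term_id,
                n_genes_matched=term.n_genes_matched,
                p_domain=p_draw,
                n_trials=n_fg_total,
                n_hits=hits_fg,
                expected=expected,
                fold_enrichment=fold,
                p_binomial=None,
                p_adjusted=math.nan,
                p_hypergeometric=hypergeometric_tail(n_bg_total, n_fg_total, hits_bg, hits_fg),
                n_background=n_bg_total,
                n_foreground=n_fg_total,
                hits_background=hits_bg,
                hits_foreground=hits_fg,
            )
        )
    adj = adjust_bh([r.p_hypergeometric for r in rows])
    rows = [replace(r, p_adjusted=max(q, r.p_hypergeometric)) for r, q in zip(rows, adj)]
    rows.sort(key=lambda r: (r.p_hypergeometric, r.term_id))
    return rows


def results_to_frame(rows: Sequence[EnrichmentRow]) -> "pd.DataFrame":
    """Tabular view of enrichment rows.

    Columns: term_id, n_genes, p_domain, n_trials, n_hits, expected,
    fold_enrichment, p_binomial, p_adjusted, and — when any row carries
    them — p_hypergeometric, N_bg, N_fg, n_bg, n_fg.
    """
    import pandas as pd

    data = {
        "term_id": [r.term_id for r in rows],
        "n_genes": [r.n_genes_matched for r in rows],
        "p_domain": [r.p_domain for r in rows],
        "n_trials": [r.n_trials for r in rows],
        "n_hits": [r.n_hits for r in rows],
        "expected": [r.expected for r in rows],
        "fold_enrichment": [r.fold_enrichment for r in rows],
        "p_binomial": [r.p_binomial for r in rows],
        "p_adjusted": [r.p_adjusted for r in rows],
    }
    if any(r.p_hypergeometric is not None for r in rows):
        data["p_hypergeometric"] = [r.p_hypergeometric for r in rows]
        data["N_bg"] = [r.n_background for r in rows]
        data["N_fg"] = [r.n_foreground for r in rows]
        data["n_bg"] = [r.hits_background for r in rows]
        data["n_fg"] = [r.hits_foreground for r in rows]
    return pd.DataFrame(data)


def write_results(path, rows: Sequence[EnrichmentRow]) -> None:
    """Write the deterministic tab-delimited results table."""
    results_to_frame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def attach_hypergeometric(
    binomial_rows: list[EnrichmentRow], hyper_rows: list[EnrichmentRow]
) -> list[EnrichmentRow]:
    """Merge hypergeometric columns onto binomial rows by term_id."""
    by_term = {r.term_id: r for r in hyper_rows}
    out = []
    for r in binomial_rows:
        h = by_term.get(r.term_id)
        if h is None:
            out.append(r)
            continue
        out.append(
            replace(
                r,
                p_hypergeometric=h.p_hypergeometric,
                n_background=h.n_background,
                n_foreground=h.n_foreground,
                hits_background=h.hits_background,
                hits_foreground=h.hits_foreground,
            )
        )
    return out
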