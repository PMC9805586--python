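# Methods

## Coordinates and interval semantics

All internal coordinates are 0-based half-open (BED-native); GTF input
(1-based closed) is converted on read, with the TSS taken as the 0-based
position of the annotated 5′ end (GTF `start−1` on `+`, `end−1` on `−`).
`merge` coalesces overlapping *and* book-ended intervals, because every
downstream quantity (p, p₂) depends only on covered bases, for which the
coalesced form is canonical. Strand is carried on intervals but ignored by
all interval arithmetic; it matters only when basal domains are derived
from TSSs. Chromosome names are matched exactly (no `chr1`/`1` aliasing);
a two-column rename map is the explicit escape hatch, since silent aliasing
is the classic source of quietly empty enrichment runs.

## Regulatory domains

The basal domain of a gene is `[tss − up, tss + down)` on `+` and
`[tss − down, tss + up)` on `−` (defaults up = 5 000, down = 1 000 bases),
clipped to the chromosome. The extension on each side runs to the nearest
other gene's basal boundary on that side, capped at 1 Mb and the chromosome
end. Concretely, a neighbor with basal `[x, y)` limits the right extension
of a gene with basal `[s, e)` iff `y ≥ e`, at `max(x, e)`; the left rule is
the mirror image. This single boundary rule yields the intended behaviour
in all corner cases: a neighbor whose basal boundary lies inside (or at the
shared edge of) the gene's basal interval contributes zero extension on
that side; two genes with identical TSSs bound each other at their shared
basal boundaries; a gene whose basal is fully covered by a neighbor's still
keeps its own basal domain (basal domains are unconditional and are never
shrunk). A neighbor whose basal lies strictly *inside* the gene's basal
imposes no constraint — the extension region beyond the basal never touches
it. Neighbor bounding is strand-agnostic. When an annotation carries
multiple transcripts per gene, the reader reduces to the 5′-most TSS per
gene; this is a documented convention, not a property of the model, and
TSS-source differences of a few hundred bases are negligible against the
megabase scale of the extensions.

The per-gene computation considers all other basal intervals on the
chromosome through sorted-array masks; it is quadratic per chromosome in
the worst case, which is irrelevant at annotation sizes up to a few
thousand genes per chromosome.

## Enrichment tests

`binomial_tail` and `hypergeometric_tail` are exact upper tails
(scipy's `binom.sf` / `hypergeom.sf`); no normal approximation is used at
any N, since N is a region count (rarely beyond 10⁶) and the exact tails
are cheap. Returned P-values are clamped into `(0, 1]`: an underflowed tail
is reported as the smallest positive float rather than 0, so log-scale
consumers never see −inf.

Each input region is one Bernoulli trial: input regions are deliberately
*not* merged with each other, only the term domains are. The default hit
rule is the region midpoint, `floor((start+end)/2)` — deterministic and
unambiguous (a midpoint lies in exactly one merged domain or none), whereas
any-overlap (offered as a mode) can credit one region to a domain it barely
touches. Under a background or exclude restriction, trials stay whole
regions: N₂ counts original regions whose midpoint falls in the universe U
and n₂ those falling in `domain ∩ U`; only domains are clipped when
computing p₂ = |domain ∩ U| / |U|. A whole-genome background and an empty
exclude set reproduce the unrestricted run bit for bit (asserted in the
tests). N₂ = 0 (background disjoint from the input) and a zero-length
universe are user errors; n₂ > 0 with p₂ = 0 would mean hit counting
disagrees with coverage and raises an internal-consistency error.

The hypergeometric test enforces the foreground-⊆-background requirement by
exact `(chrom, start, end)` identity with multiplicity — the testable proxy
for index-set inclusion. Multiple-testing adjustment is Benjamini–Hochberg
across all terms of one run (delegated to statsmodels); the collection-wide
FDR is the least surprising default and is labelled as such, the raw
P-value is always reported alongside.

Fold enrichment is n / (N·p); when the expectation is zero it is reported
as NaN rather than inventing a value.

## Association records

Distances are measured from the region midpoint to the TSS, signed
strand-relatively (negative = the midpoint is 5′/upstream of the TSS), so
histograms read identically for `+` and `−` genes. The default histogram
bins are half-open between edges ±5 kb, ±50 kb, ±500 kb. The association
table and the enrichment counts are mutually consistent: a term's n_hits
equals the number of distinct input regions associated with at least one of
its genes under the same hit mode (asserted in the tests).

## Synthetic study conditions

The generator's defaults define the conditions under which the statistical
properties are demonstrated: a 2 × 5 Mb genome, 200 genes (≈50 kb TSS
spacing, so neighbor bounding — not the 1 Mb cap — typically limits
extensions, as in gene-dense regions of real genomes), 20 gene sets of 10
genes, and 500 regions of width 50 with uniformly drawn midpoints. Under
the default domain parameters a ten-gene term domain covers roughly 7–14%
of this genome, so planted-signal scenarios operate near p ≈ 0.1. Region
midpoints are drawn uniformly over the admissible interior of each
chromosome (so a fixed-width region never has to be clipped, and the
midpoint — the quantity the hit rule tests — is exactly uniform); planting
draws the chosen fraction of midpoints uniformly from the covered bases of
the target domain. One integer seed drives everything through distinct
named numpy Generator streams; the same seed yields byte-identical files.

What the fixtures do *not* emulate: clustered genes, chromosome-scale
covariates (GC, gaps), autocorrelated or width-heterogeneous region sets,
and correlated gene sets beyond random overlap. Passing calibration on
these fixtures therefore shows the machinery is correct under the model's
own null, not that uniform placement is an adequate null for any particular
real dataset — that is precisely why the background/exclude mechanism
exists.

## Calibration and recovery checks

The type-I check runs 1 000 replicates; each draws a fresh set of 2 000
uniform regions and evaluates a single term (cycling through the
collection), so the 1 000 rejection indicators are independent and the
exact binomial 99% interval around α = 0.05 applies. Evaluating all terms
per replicate would correlate the indicators through the shared region set.
2 000 trials per replicate keep the discreteness gap of the exact test
small (the attained level at nominal 0.05 stays above ≈0.042 at these
domain fractions). The recovery check plants half of 500 regions into one
term's domain and requires that term to rank first; the
binomial/hypergeometric agreement check tiles a 250 kb single-term domain
and its complement with width-100 background regions (≈2 000 of them
against 30 foreground draws, so the without-replacement correction is
small) and compares the two tests on the identical counts. The
improper-background check samples regions from a 200 kb sub-universe and
verifies the genome-wide P-value is anticonservative relative to the
correctly restricted one — the reason a deliberate background matters.

The acceptance script reports these same quantities at slightly reduced
replicate counts (500 null replicates, 50 recovery replicates), its choice
of problem sizes for a quick single-CPU reproduction.

## Command-line interface

`localgreat run/simulate/domains` are thin wrappers over the library.
Results are written to files and logs to standard error; the manifest
records parameters, input SHA-256 checksums and machine-readable reader
warning tallies, and contains no timestamps, so re-running with identical
inputs reproduces every output byte-identically. Exit codes separate usage
(2), parse (3), validation (4) and internal (5) failures.

## Known limitations

Only the basal-plus-extension association rule is implemented (no
two-nearest-genes / single-nearest-gene variants, no curated per-gene
domains). Gene sets arrive flattened (GMT); there is no ontology-graph
awareness or term decorrelation, so parent/child terms are tested — and
BH-adjusted — as if independent. Background and exclude cannot be combined
in one run. Readers are whole-file; there is no tabix/random access. The
hypergeometric mode requires literal coordinate identity between foreground
and background regions.
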