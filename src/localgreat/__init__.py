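"""localgreat: GREAT-style functional enrichment on genomic regions, locally.

Builds per-gene regulatory domains (basal plus extension) from a TSS
annotation, merges them into per-term region sets, and tests input regions
for enrichment with the binomial model — optionally restricted to a
background or exclude universe — plus the classic hypergeometric
background test.
"""

from .association import AssociationRecord, AssociationTable, associate, distance_summary
from .domains import (
    DomainParams,
    GeneAnnotation,
    RegulatoryDomain,
    TermDomain,
    basal_domain,
    extend_domains,
    term_domain,
)
from .enrichment import (
    BackgroundSpec,
    EnrichmentRow,
    adjust_bh,
    attach_hypergeometric,
    binomial_tail,
    hypergeometric_tail,
    results_to_frame,
    run_great,
    run_great_hypergeometric,
    write_results,
)
from .errors import (
    AnnotationMismatchError,
    ConsistencyError,
    FormatError,
    InputError,
    LocalGreatError,
    SubsetViolationError,
)
from .fixtures import (
    FixtureConfig,
    make_gene_sets,
    make_genes,
    make_genome,
    make_regions,
    write_fixture,
)
from .formats import (
    GeneSet,
    GeneSetCollection,
    read_bed,
    read_chrom_sizes,
    read_gene_table,
    read_gmt,
    read_gtf_genes,
    write_bed,
    write_chrom_sizes,
    write_gene_table,
    write_gmt,
)
from .intervals import (
    Genome,
    GenomicInterval,
    IntervalSet,
    count_hits,
    intersect,
    merge,
    subtract,
    total_length,
)

__version__ = "0.1.0"


def build_term_domains(collection, domains, genome):
    """Convenience: one merged TermDomain per gene set in a collection."""
    return [
        term_domain(set(gs.members), domains, genome, term_id=gs.term_id)
        for gs in collection
    ]


__all__ = [name for name in dir() if not name.startswith("_")]
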