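"""Statistical core: tails vs summation oracles, restriction identities,
binomial/hypergeometric agreement, and error handling."""

import math

import numpy as np
import pytest

from localgreat import (
    BackgroundSpec,
    GenomicInterval,
    InputError,
    IntervalSet,
    SubsetViolationError,
    TermDomain,
    adjust_bh,
    binomial_tail,
    hypergeometric_tail,
    merge,
    run_great,
    run_great_hypergeometric,
    total_length,
)
from localgreat.enrichment import attach_hypergeometric


def binom_tail_oracle(n, N, p):
    """Direct pmf summation Pr(X >= n) via the binomial coefficient."""
    total = 0.0
    for k in range(n, N + 1):
        total += math.comb(N, k) * p**k * (1 - p) ** (N - k)
    return total


def hyper_tail_oracle(N_bg, N_fg, n_bg, n_fg):
    """Enumeration of Pr(X >= n_fg) for X ~ Hyper(N_bg, n_bg, N_fg)."""
    total = 0.0
    denom = math.comb(N_bg, N_fg)
    for k in range(n_fg, min(N_fg, n_bg) + 1):
        if N_fg - k > N_bg - n_bg:
            continue
        total += math.comb(n_bg, k) * math.comb(N_bg - n_bg, N_fg - k) / denom
    return total


class TestBinomialTail:
    def test_zero_hits_is_one(self):
        assert binomial_tail(0, 1000, 0.3) == 1.0
        assert binomial_tail(0, 0, 0.0) == 1.0

    def test_all_hits_certain_success(self):
        assert binomial_tail(10, 10, 1.0) == 1.0

    def test_matches_pmf_summation(self):
        assert binomial_tail(5, 10, 0.2) == pytest.approx(
            binom_tail_oracle(5, 10, 0.2), rel=1e-13
        )
        rng = np.random.default_rng(61)
        for _ in range(50):
            N = int(rng.integers(1, 200))
            n = int(rng.integers(0, N + 1))
            p = float(rng.uniform(0.01, 0.99))
            assert binomial_tail(n, N, p) == pytest.approx(
                binom_tail_oracle(n, N, p), rel=1e-11
            )

    def test_monotone_nonincreasing_in_hits(self):
        for N, p in [(25, 0.3), (50, 0.05)]:
            tails = [binomial_tail(n, N, p) for n in range(N + 1)]
            assert all(a >= b for a, b in zip(tails, tails[1:]))

    def test_complement_identity(self):
        for N, p in [(12, 0.4), (50, 0.1)]:
            for n in range(1, N + 1):
                lower = binom_tail_oracle(0, N, p) - binom_tail_oracle(n, N, p)
                assert binomial_tail(n, N, p) + lower == pytest.approx(1.0, abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(InputError):
            binomial_tail(5, 4, 0.1)
        with pytest.raises(InputError):
            binomial_tail(1, 10, 1.5)


class TestHypergeometricTail:
    def test_zero_foreground_hits_is_one(self):
        assert hypergeometric_tail(20, 5, 8, 0) == 1.0

    def test_draw_all_degenerate(self):
        # drawing the whole background: hits are forced to equal n_bg
        assert hypergeometric_tail(20, 20, 8, 8) == pytest.approx(1.0)
        with pytest.raises(InputError):
            hypergeometric_tail(20, 20, 8, 9)

    def test_matches_enumeration(self):
        assert hypergeometric_tail(20, 5, 8, 4) == pytest.approx(
            hyper_tail_oracle(20, 5, 8, 4), rel=1e-13
        )
        rng = np.random.default_rng(67)
        for _ in range(50):
            N_bg = int(rng.integers(2, 60))
            N_fg = int(rng.integers(1, N_bg + 1))
            n_bg = int(rng.integers(0, N_bg + 1))
            n_fg = int(rng.integers(0, min(N_fg, n_bg) + 1))
            assert hypergeometric_tail(N_bg, N_fg, n_bg, n_fg) == pytest.approx(
                hyper_tail_oracle(N_bg, N_fg, n_bg, n_fg), rel=1e-11, abs=1e-300
            )

    def test_precondition_violations(self):
        with pytest.raises(InputError):
            hypergeometric_tail(10, 11, 5, 2)
        with pytest.raises(InputError):
            hypergeometric_tail(10, 5, 11, 2)


class TestAdjustBH:
    def test_single_and_equal_inputs_unchanged(self):
        assert adjust_bh([0.01]) == [0.01]
        assert adjust_bh([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])
        assert adjust_bh([]) == []

    def test_matches_step_up_formula(self):
        ps = [0.01, 0.02, 0.03, 0.04]
        m = len(ps)
        # hand step-up: q_(i) = min over j>=i of p_(j) * m / j, clipped at 1
        order = sorted(range(m), key=lambda i: ps[i])
        q = [0.0] * m
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, ps[i] * m / rank)
            q[i] = running
        assert adjust_bh(ps) == pytest.approx(q)

    def test_monotone_and_order_preserving(self):
        rng = np.random.default_rng(71)
        ps = rng.uniform(size=30).tolist()
        qs = adjust_bh(ps)
        assert all(0 < q <= 1 for q in qs)
        assert all(q >= p for p, q in zip(ps, qs))
        # order preserved: adjusting a permutation permutes the output
        perm = rng.permutation(30)
        qs_perm = adjust_bh([ps[i] for i in perm])
        assert qs_perm == pytest.approx([qs[i] for i in perm])


def _term(genome, ivs, term_id="T1", n_genes=3):
    dom = merge(IntervalSet([GenomicInterval(*t) for t in ivs], genome))
    return TermDomain(term_id, dom, total_length(dom) / genome.total_size, n_genes)


def _width1_regions(genome, positions):
    return IntervalSet(
        [GenomicInterval(c, p, p + 1, ".", f"r{i}") for i, (c, p) in enumerate(positions)],
        genome,
    )


class TestRunGreat:
    def test_toy_fixture_matches_oracle(self, mb_genome):
        term = _term(mb_genome, [("chr1", 0, 200_000)])
        inside = [("chr1", x) for x in (10, 50_000, 100_000, 150_000, 199_999)]
        outside = [("chr1", x) for x in (200_000, 300_000, 500_000, 700_000, 999_999)]
        regions = _width1_regions(mb_genome, inside + outside)
        [row] = run_great(regions, [term], mb_genome)
        assert (row.n_hits, row.n_trials, row.p_domain) == (5, 10, 0.2)
        assert row.expected == pytest.approx(2.0)
        assert row.fold_enrichment == pytest.approx(2.5)
        assert row.p_binomial == pytest.approx(binom_tail_oracle(5, 10, 0.2), rel=1e-12)
        assert row.p_adjusted == row.p_binomial  # single term

    def test_rows_sorted_by_pvalue_then_term(self, mb_genome):
        t1 = _term(mb_genome, [("chr1", 0, 100_000)], "B")
        t2 = _term(mb_genome, [("chr1", 0, 100_000)], "A")
        # A and B identical (tie broken by id); C covers 90% so Pr(X>=9)
        # at p=0.9 exceeds the tie's Pr(X>=1) at p=0.1
        t3 = _term(mb_genome, [("chr1", 0, 900_000)], "C")
        regions = _width1_regions(mb_genome, [("chr1", x) for x in range(0, 1_000_000, 100_000)])
        rows = run_great(regions, [t3, t1, t2], mb_genome)
        assert [r.term_id for r in rows] == ["A", "B", "C"]

    def test_background_whole_genome_reproduces_unrestricted(self, mb_genome):
        rng = np.random.default_rng(73)
        term = _term(mb_genome, [("chr1", 100_000, 300_000), ("chr1", 600_000, 650_000)])
        regions = _width1_regions(
            mb_genome, [("chr1", int(x)) for x in rng.integers(0, 1_000_000, 200)]
        )
        base = run_great(regions, [term], mb_genome)
        wg = run_great(
            regions, [term], mb_genome, BackgroundSpec.background(mb_genome.whole_genome())
        )
        ex = run_great(
            regions, [term], mb_genome, BackgroundSpec.exclude(IntervalSet.empty(mb_genome))
        )
        assert wg == base and ex == base  # bit-for-bit dataclass equality

    def test_exclude_restricts_universe(self, mb_genome):
        term = _term(mb_genome, [("chr1", 0, 200_000)])
        regions = _width1_regions(
            mb_genome, [("chr1", x) for x in (10, 100_000, 250_000, 400_000)]
        )
        excl = IntervalSet([GenomicInterval("chr1", 500_000, 1_000_000)], mb_genome)
        [row] = run_great(regions, [term], mb_genome, BackgroundSpec.exclude(excl))
        assert row.n_trials == 4 and row.n_hits == 2
        assert row.p_domain == pytest.approx(200_000 / 500_000)

    def test_p2_width_identity_for_disjoint_background(self, mb_genome):
        """With disjoint background regions, p2 equals the width-sum ratio."""
        rng = np.random.default_rng(79)
        term = _term(mb_genome, [("chr1", 200_000, 500_000)])
        starts = np.arange(0, 1_000_000, 5_000)
        widths = rng.integers(100, 2_000, size=starts.size)
        bg = IntervalSet(
            [GenomicInterval("chr1", int(s), int(s + w)) for s, w in zip(starts, widths)],
            mb_genome,
        )
        regions = _width1_regions(mb_genome, [("chr1", int(s)) for s in starts[::7]])
        [row] = run_great(regions, [term], mb_genome, BackgroundSpec.background(bg))
        in_dom = sum(
            max(0, min(s + w, 500_000) - max(s, 200_000)) for s, w in zip(starts, widths)
        )
        assert row.p_domain == pytest.approx(in_dom / widths.sum(), rel=1e-12)

    def test_error_when_background_misses_input(self, mb_genome):
        term = _term(mb_genome, [("chr1", 0, 200_000)])
        regions = _width1_regions(mb_genome, [("chr1", 900_000)])
        bg = IntervalSet([GenomicInterval("chr1", 0, 100_000)], mb_genome)
        with pytest.raises(InputError, match="background does not cover"):
            run_great(regions, [term], mb_genome, BackgroundSpec.background(bg))

    def test_empty_region_set_rejected(self, mb_genome):
        with pytest.raises(InputError):
            run_great(IntervalSet.empty(mb_genome), [], mb_genome)

    def test_empty_term_domain_scores_one(self, mb_genome):
        empty = TermDomain("T0", IntervalSet.empty(mb_genome), 0.0, 0, empty=True)
        regions = _width1_regions(mb_genome, [("chr1", 10)])
        [row] = run_great(regions, [empty], mb_genome)
        assert row.p_binomial == 1.0 and row.n_hits == 0


class TestHypergeometricRun:
    def test_foreground_equals_background_all_ones(self, mb_genome):
        term = _term(mb_genome, [("chr1", 0, 300_000)])
        regions = _width1_regions(mb_genome, [("chr1", x) for x in range(0, 1_000_000, 50_000)])
        rows = run_great_hypergeometric(regions, regions, [term], mb_genome)
        assert all(r.p_hypergeometric == pytest.approx(1.0) for r in rows)

    def test_subset_violation_lists_regions(self, mb_genome):
        bg = _width1_regions(mb_genome, [("chr1", 100), ("chr1", 200)])
        fg = _width1_regions(mb_genome, [("chr1", 100), ("chr1", 300)])
        with pytest.raises(SubsetViolationError, match="chr1:300"):
            run_great_hypergeometric(fg, bg, [], mb_genome)

    def test_counts_match_enumeration_case(self, mb_genome):
        # engineered to give N_bg=20, N_fg=5, n_bg=8, n_fg=4
        term = _term(mb_genome, [("chr1", 0, 80_000)])
        bg_pos = [("chr1", 10_000 * i + 500) for i in range(20)]  # first 8 in domain
        fg_pos = [bg_pos[i] for i in (0, 2, 4, 6, 15)]
        rows = run_great_hypergeometric(
            _width1_regions(mb_genome, fg_pos), _width1_regions(mb_genome, bg_pos), [term], mb_genome
        )
        [row] = rows
        assert (row.n_background, row.n_foreground) == (20, 5)
        assert (row.hits_background, row.hits_foreground) == (8, 4)
        assert row.p_hypergeometric == pytest.approx(
            hyper_tail_oracle(20, 5, 8, 4), rel=1e-12
        )

    def test_attach_hypergeometric_merges_columns(self, mb_genome):
        term = _term(mb_genome, [("chr1", 0, 300_000)])
        bg = _width1_regions(mb_genome, [("chr1", x) for x in range(0, 1_000_000, 20_000)])
        fg = _width1_regions(mb_genome, [("chr1", x) for x in range(0, 600_000, 60_000)])
        brows = run_great(fg, [term], mb_genome, BackgroundSpec.background(bg))
        hrows = run_great_hypergeometric(fg, bg, [term], mb_genome)
        merged = attach_hypergeometric(brows, hrows)
        assert merged[0].p_binomial == brows[0].p_binomial
        assert merged[0].p_hypergeometric == hrows[0].p_hypergeometric


def tiled_background(genome, domain, width, step_in, step_out):
    """Equal-width disjoint regions fully inside or fully outside a domain."""
    from localgreat import subtract

    ivs = []
    for iv in domain:
        for s in range(iv.start, iv.end - width + 1, step_in):
            ivs.append(GenomicInterval(iv.chrom, s, s + width))
    outside = subtract(genome.whole_genome(), domain)
    for iv in outside:
        for s in range(iv.start, iv.end - width + 1, step_out):
            ivs.append(GenomicInterval(iv.chrom, s, s + width))
    return IntervalSet(ivs, genome)


class TestBinomialHypergeometricAgreement:
    def make_fixture(self, mb_genome, widths=(100, 100)):
        """Background tiles in/out of a 250 kb domain; mild planted signal."""
        w_in, w_out = widths
        term = _term(mb_genome, [("chr1", 100_000, 350_000)])
        rng = np.random.default_rng(83)
        ivs = []
        for s in range(100_000, 350_000 - w_in + 1, 1_000):
            ivs.append(GenomicInterval("chr1", s, s + w_in))
        n_in = len(ivs)
        for s in list(range(0, 100_000 - w_out, 500)) + list(
            range(350_000, 1_000_000 - w_out, 500)
        ):
            ivs.append(GenomicInterval("chr1", s, s + w_out))
        bg = IntervalSet(ivs, mb_genome)
        # foreground: 30 background members, in-domain members twice as likely
        weights = np.array([2.0] * n_in + [1.0] * (len(ivs) - n_in))
        idx = rng.choice(len(ivs), size=30, replace=False, p=weights / weights.sum())
        fg = IntervalSet([ivs[i] for i in idx], mb_genome)
        return term, bg, fg

    def test_equal_width_agreement(self, mb_genome):
        term, bg, fg = self.make_fixture(mb_genome)
        [brow] = run_great(fg, [term], mb_genome, BackgroundSpec.background(bg))
        [hrow] = run_great_hypergeometric(fg, bg, [term], mb_genome)
        # equal widths: p2 reduces exactly to n_bg/N_bg
        assert brow.p_domain == pytest.approx(
            hrow.hits_background / hrow.n_background, rel=1e-12
        )
        dlog = abs(math.log10(brow.p_binomial) - math.log10(hrow.p_hypergeometric))
        assert dlog <= 0.05

    def test_heterogeneous_widths_degrade_agreement(self, mb_genome):
        term, bg, fg = self.make_fixture(mb_genome)
        [brow] = run_great(fg, [term], mb_genome, BackgroundSpec.background(bg))
        [hrow] = run_great_hypergeometric(fg, bg, [term], mb_genome)
        d_equal = abs(math.log10(brow.p_binomial) - math.log10(hrow.p_hypergeometric))

        term2, bg2, fg2 = self.make_fixture(mb_genome, widths=(400, 80))
        [brow2] = run_great(fg2, [term2], mb_genome, BackgroundSpec.background(bg2))
        [hrow2] = run_great_hypergeometric(fg2, bg2, [term2], mb_genome)
        d_het = abs(math.log10(brow2.p_binomial) - math.log10(hrow2.p_hypergeometric))
        # wider in-domain regions inflate p2 above n_bg/N_bg: agreement is
        # ordered worse, not bounded
        assert d_het > d_equal


class TestLargerBackgroundEffect:
    def test_genome_wide_p_is_anticonservative(self, mb_genome):
        """Testing genome-wide when sampling was restricted to a universe
        produces a smaller (anticonservative) P for the enriched term."""
        universe = IntervalSet([GenomicInterval("chr1", 0, 200_000)], mb_genome, merged=True)
        term = _term(mb_genome, [("chr1", 0, 100_000)])
        rng = np.random.default_rng(89)
        for _ in range(10):
            pos = rng.integers(0, 200_000, size=100)  # truly sampled within U
            regions = _width1_regions(mb_genome, [("chr1", int(x)) for x in pos])
            [gw] = run_great(regions, [term], mb_genome)
            [restricted] = run_great(
                regions, [term], mb_genome, BackgroundSpec.background(universe)
            )
            assert gw.p_binomial <= restricted.p_binomial
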