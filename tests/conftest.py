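import numpy as np
import pytest

from localgreat import Genome, GenomicInterval, IntervalSet


@pytest.fixture
def toy_genome():
    return Genome([("chr1", 10_000), ("chr2", 8_000)])


@pytest.fixture
def mb_genome():
    return Genome([("chr1", 1_000_000)])


def bool_cover(s: IntervalSet) -> dict[str, np.ndarray]:
    """Base-by-base boolean oracle of the covered bases of a set."""
    cover = {c: np.zeros(l, dtype=bool) for c, l in s.genome.items()}
    for iv in s:
        cover[iv.chrom][iv.start : iv.end] = True
    return cover


def covers_equal(a: IntervalSet, b: IntervalSet) -> bool:
    ca, cb = bool_cover(a), bool_cover(b)
    return all(np.array_equal(ca[c], cb[c]) for c in ca)


def random_interval_set(rng, genome, n, max_width=500, named=False) -> IntervalSet:
    chroms = list(genome.items())
    ivs = []
    for i in range(n):
        chrom, length = chroms[rng.integers(len(chroms))]
        w = int(rng.integers(1, min(max_width, length) + 1))
        start = int(rng.integers(0, length - w + 1))
        ivs.append(
            GenomicInterval(chrom, start, start + w, ".", f"iv{i}" if named else None)
        )
    return IntervalSet(ivs, genome)
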