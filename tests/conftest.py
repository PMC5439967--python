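import numpy as np
import pytest

from motifcoloc.intervals import GenomicInterval, IntervalSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def toy_genome():
    return {"chr1": 100_000, "chr2": 50_000}


def random_intervals(rng, genome, n, min_w=1, max_w=200, strand_mix=False):
    """Uniform random intervals over a genome dict, for oracle comparisons."""
    out = []
    chroms = list(genome)
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        w = int(rng.integers(min_w, max_w + 1))
        start = int(rng.integers(0, genome[chrom] - w))
        strand = ["+", "-", "."][int(rng.integers(3))] if strand_mix else "."
        out.append(GenomicInterval(chrom, start, start + w, strand))
    return IntervalSet(out, genome)
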