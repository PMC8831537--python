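import numpy as np
import pytest

from glireg.intervals import GenomicInterval, PeakSet
from glireg.simulate import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_sim():
    """Reduced simulation configuration for fast pipeline tests."""
    return SimConfig(
        seed=11,
        n_chroms=1,
        chrom_length=20_000_000,
        n_genes=60,
        n_tads=40,
        n_gbrs=400,
        n_true_targets=10,
        n_retention_genes=15,
        reads_per_gene=200,
        n_footprints=300,
    )


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=100_000, max_len=500):
    """Uniform random named intervals for oracle comparisons."""
    out = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length, f"iv_{i}"))
    return out


@pytest.fixture
def random_peaks(rng):
    def make(n, label="peaks", **kw):
        return PeakSet(label, random_intervals(rng, n, **kw))

    return make
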