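import numpy as np
import pandas as pd
import pytest

from sslineage import synth
from sslineage.config import PipelineConfig


@pytest.fixture(scope="session")
def epi_seed1():
    return synth.gen_epigenome(seed=1)


@pytest.fixture(scope="session")
def cellline_counts_seed1(epi_seed1):
    return synth.gen_cellline_counts(epi_seed1, seed=1)


@pytest.fixture(scope="session")
def cohort_seed3():
    epi = synth.gen_epigenome(seed=3)
    tpm, clinical, truth = synth.gen_tumor_cohort(epi, seed=3)
    return epi, tpm, clinical, truth


@pytest.fixture
def default_config():
    return PipelineConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_peaks(rng, n, bound=10_000, max_len=400, chroms=("chr1", "chr2")):
    from sslineage.intervals import GenomicInterval, SignalPeak

    peaks = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, bound - max_len))
        length = int(rng.integers(1, max_len))
        peaks.append(SignalPeak(GenomicInterval(chrom, start, start + length),
                                float(rng.uniform(0, 100))))
    return peaks
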