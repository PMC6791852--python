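"""Shared fixtures: a desk-scale synthetic dataset and small building blocks."""

import numpy as np
import pytest

from crckit.intervals import GenomeAssembly, GenomicInterval, RegionSet, Transcript
from crckit.simulate import ScreenConfig, SynthConfig, simulate_dataset


def mini_config(seed: int = 0, **overrides) -> SynthConfig:
    """A reduced dataset that exercises every stage in a few seconds."""
    defaults = dict(
        seed=seed,
        genome_length=1_500_000,
        n_genes=50,
        n_inactive_genes=8,
        n_tfs=8,
        n_atac_peaks=200,
        driver_edge_count=40,
        nondriver_edge_count=10,
        read_depth=200_000,
        n_spurious_tfchip_peaks=10,
        screen=ScreenConfig(n_genes=100, planted_down=8, planted_up=4),
    )
    defaults.update(overrides)
    return SynthConfig(**defaults)


@pytest.fixture(scope="session")
def mini_dataset():
    return simulate_dataset(mini_config(seed=7))


@pytest.fixture
def toy_assembly():
    return GenomeAssembly({"chr1": 100_000, "chr2": 50_000})


def iv(start, end, chrom="chr1", **kw):
    return GenomicInterval(chrom, start, end, **kw)


def tx(tss, strand="+", gene="G1", tid="T1", chrom="chr1", length=1000):
    if strand == "+":
        span = GenomicInterval(chrom, tss, tss + length, strand="+")
    else:
        span = GenomicInterval(chrom, tss - length + 1, tss + 1, strand="-")
    return Transcript(tid, gene, span)


def random_region_set(rng, n=20, chrom_len=10_000, max_len=300) -> RegionSet:
    starts = rng.integers(0, chrom_len - max_len, size=n)
    lens = rng.integers(1, max_len, size=n)
    return RegionSet([GenomicInterval("chr1", int(s), int(s + l))
                      for s, l in zip(starts, lens)])
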