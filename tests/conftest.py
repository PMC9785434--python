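import numpy as np
import pandas as pd
import pytest

from ocratlas.intervals import GenomeAnnotation, IntervalSet
from ocratlas.synth import SynthConfig, simulate_study


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    """A scaled-down study: quick to simulate, every signal still recoverable."""
    return SynthConfig(
        n_chroms=2,
        chrom_length=400_000,
        n_genes=60,
        n_peaks_per_group=120,
        n_differential=40,
        depth_per_sample=30_000,
        n_de_genes=20,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return simulate_study(small_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_interval_set(rng, n, chrom_sizes, max_width=500):
    """Random intervals over the given chromosomes."""
    names = sorted(chrom_sizes)
    chroms = rng.choice(names, size=n)
    widths = rng.integers(1, max_width + 1, size=n)
    sizes = np.array([chrom_sizes[c] for c in chroms])
    starts = (rng.random(n) * (sizes - widths)).astype(np.int64)
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": starts + widths,
            "name": [f"iv_{i}" for i in range(n)],
        }
    )
    return IntervalSet(df, chrom_sizes)


def toy_annotation() -> GenomeAnnotation:
    """Two genes on one chromosome, hand-placed for exact assertions.

    gene_a: + strand, [10000, 16000), TSS 10000, two exons with UTRs.
    gene_b: - strand, [30000, 36000), TSS 35999.
    """
    genes = pd.DataFrame(
        {
            "gene_id": ["gene_a", "gene_b"],
            "chrom": ["chr1", "chr1"],
            "strand": ["+", "-"],
            "start": [10000, 30000],
            "end": [16000, 36000],
            "tss": [10000, 35999],
        }
    )
    exons = pd.DataFrame(
        {
            "gene_id": ["gene_a", "gene_a", "gene_b", "gene_b"],
            "chrom": ["chr1"] * 4,
            "start": [10000, 14000, 30000, 34000],
            "end": [11000, 16000, 32000, 36000],
        }
    )
    utr5 = pd.DataFrame(
        {"gene_id": ["gene_a", "gene_b"], "chrom": ["chr1", "chr1"],
         "start": [10000, 35800], "end": [10100, 36000]}
    )
    utr3 = pd.DataFrame(
        {"gene_id": ["gene_a", "gene_b"], "chrom": ["chr1", "chr1"],
         "start": [15850, 30000], "end": [16000, 30150]}
    )
    return GenomeAnnotation(genes, exons, utr5, utr3, {"chr1": 100_000})
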