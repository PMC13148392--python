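import numpy as np
import pytest

from recgain.genome import GeneticMap


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def two_chrom_map():
    """A small two-chromosome map with evenly spaced loci."""
    n = 40
    pos = np.concatenate([np.linspace(2.5, 100.0, n), np.linspace(3.0, 120.0, n)])
    return GeneticMap(
        chrom_names=("1", "2"),
        chrom_starts=np.array([0, n, 2 * n]),
        positions=pos,
        lengths=np.array([100.0, 120.0]),
        locus_ids=np.array([f"l{i}" for i in range(2 * n)], dtype=object),
    )


@pytest.fixture
def single_locus_map():
    return GeneticMap(
        chrom_names=("1",),
        chrom_starts=np.array([0, 1]),
        positions=np.array([10.0]),
        lengths=np.array([10.0]),
        locus_ids=np.array(["l0"], dtype=object),
    )


@pytest.fixture
def tiny_length_map():
    """Loci on a vanishingly short chromosome: crossovers essentially never occur."""
    n = 12
    return GeneticMap(
        chrom_names=("1",),
        chrom_starts=np.array([0, n]),
        positions=np.linspace(1e-9, 1e-8, n),
        lengths=np.array([1e-8]),
        locus_ids=np.array([f"l{i}" for i in range(n)], dtype=object),
    )
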