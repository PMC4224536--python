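import numpy as np
import pytest

from neratio.datatypes import GenotypeMatrix, SequenceAlignment
from neratio.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small but realistic synthetic dataset, shared across tests."""
    config = SimConfig(seed=20140903, n_individuals=24, n_loci=5, theta_msat=5.0)
    return simulate_dataset(config)


@pytest.fixture
def toy_alignment():
    return SequenceAlignment(
        ["a", "b", "c", "d"],
        ["ACGTACGT", "ACGTACGT", "AGGTACGT", "ACGTACGA"],
    )


@pytest.fixture
def toy_genotypes():
    alleles = np.array(
        [
            [[10, 12], [7, 7]],
            [[12, 14], [7, 8]],
            [[10, 10], [8, 8]],
        ]
    )
    return GenotypeMatrix(["i1", "i2", "i3"], ["locA", "locB"], alleles)
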