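import numpy as np
import pytest

from introkit.genio import HaplotypePanel, PopulationMap


@pytest.fixture
def toy_panel():
    """3 samples x 4 sites, phased, no missing data."""
    alleles = np.array(
        [
            [0, 1, 0, 1],
            [0, 0, 0, 1],
            [1, 1, 0, 0],
            [1, 0, 1, 0],
            [0, 1, 1, 1],
            [0, 1, 0, 1],
        ],
        dtype=np.int8,
    )
    return HaplotypePanel(
        chrom="chr1",
        positions=np.array([5, 10, 15, 20]),
        alleles=alleles,
        sample_ids=["s1", "s2", "s3"],
        phased=True,
    )


@pytest.fixture
def toy_popmap():
    return PopulationMap(
        assignments={"s1": "POP1", "s2": "POP1", "s3": "POP2"},
    )


def make_panel(alleles, positions=None, chrom="chr1", prefix="s"):
    alleles = np.asarray(alleles, dtype=np.int8)
    n_samples = alleles.shape[0] // 2
    if positions is None:
        positions = np.arange(1, alleles.shape[1] + 1)
    return HaplotypePanel(
        chrom=chrom,
        positions=np.asarray(positions),
        alleles=alleles,
        sample_ids=[f"{prefix}{i}" for i in range(n_samples)],
        phased=True,
    )
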