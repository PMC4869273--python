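import numpy as np
import pytest

from mhctyper.catalogue import Allele, AlleleCatalogue
from mhctyper.simulate import SimConfig, simulate_catalogue


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_catalogue():
    """Three handmade alleles: two classical, one non-classical."""
    return AlleleCatalogue(
        alleles=[
            Allele("BoLA-2*01601", "ATGGCTTGCAAGGCTTCATCAGGACTCGGACTCGTTTGCAAG" * 3,
                   gene_label="2", class_kind="classical"),
            Allele("BoLA-6*01402", "ATGCTTTGCGACGCTTCAACAGGACTCGGACACGTTTGCATG" * 3,
                   gene_label="6", class_kind="classical"),
            Allele("BoLA-NC1*00101", "ATGGTTCCTATTGCTTCAACTGGACTCGGACACGTATGCTAA" * 3,
                   gene_label="NC1", class_kind="nonclassical"),
        ],
        version_tag="tiny",
    )


@pytest.fixture
def sim_catalogue(rng):
    return simulate_catalogue(SimConfig(seed=11), np.random.default_rng(11))
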