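import numpy as np
import pytest

from apashift.genome_model import GeneModel, GenomicInterval
from apashift.synthetic_data import SimConfig, simulate_dataset


def make_gene(gene_id="g1", chrom="chr1", strand="+", exons=((1000, 1400), (2000, 3000))):
    return GeneModel(
        gene_id,
        GenomicInterval(chrom, exons[0][0], exons[-1][1], strand),
        tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
    )


@pytest.fixture
def plus_gene():
    return make_gene(strand="+")


@pytest.fixture
def minus_gene():
    return make_gene(strand="-")


@pytest.fixture(scope="session")
def noiseless_dataset():
    """200 genes, no noise, distal fraction 0.6 -> 0.3 in targets (so the
    expected distal/proximal double ratio is exactly 0.5)."""
    cfg = SimConfig(seed=11, log2_noise_sd=0.0, distal_fraction_kd=0.3)
    return cfg, *simulate_dataset(cfg)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default study conditions: 200 genes, 20% targets, 0.6 -> 0.2,
    log2 noise sd 0.15, two experiments."""
    cfg = SimConfig(seed=7)
    return cfg, *simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
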