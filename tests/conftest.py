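import numpy as np
import pytest

from sweepload import lrt_classifier as lrt
from sweepload import synthetic_data as sd


@pytest.fixture(scope="session")
def star3_tree() -> lrt.ScaledTree:
    """Three-taxon star tree for brute-force likelihood oracles."""
    return lrt.ScaledTree("(human:0.3,euth02:0.2,euth03:0.4);")


@pytest.fixture(scope="session")
def deep_tree() -> lrt.ScaledTree:
    """20-taxon caterpillar with ample depth for conservation power."""
    taxa = ["human"] + [f"euth{i:02d}" for i in range(2, 21)]
    nwk = taxa[0] + ":0.2"
    for t in taxa[1:]:
        nwk = f"({nwk},{t}:0.2):0.1"
    return lrt.ScaledTree(nwk + ";")


@pytest.fixture(scope="session")
def small_cfg() -> sd.SynthConfig:
    """Reduced synthetic-genome configuration for fast pipeline tests."""
    return sd.SynthConfig(
        seed=1234,
        n_chroms=2,
        chrom_length=30_000_000,
        gene_spacing=100_000,
        gene_codons=120,
        n_syn_snps=4_000,
        n_nonsyn_snps=4_000,
        n_sweep_regions=12,
        n_hotspots=10,
        n_alignment_genes=4,
    )


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    return sd.make_genome(small_cfg)


@pytest.fixture(scope="session")
def small_snps(small_cfg, small_genome):
    return sd.make_snps(small_cfg, small_genome)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(97531)
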