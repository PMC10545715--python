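import numpy as np
import pytest

from dualseq.config import QualityModel, SimulationConfig
from dualseq.simulate import simulate_genomes, simulate_reads


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale mixed sample: 5 kb pathogen, 10 kb host, one timepoint."""
    return SimulationConfig(
        seed=7,
        pathogen_genome_len=5_000,
        host_genome_len=10_000,
        n_genes_host=20,
        n_genes_pathogen=10,
        timepoints=("0h",),
        pathogen_read_fraction=(0.05,),
        replicates_per_timepoint=1,
        reads_per_sample=600,
        snp_divergence_rate=0.003,
        indel_divergence_rate=1e-4,
        n_snp_hotspots=0,
        snp_hotspot_fraction=0.0,
    )


@pytest.fixture(scope="session")
def small_world(small_cfg):
    genomes, truth = simulate_genomes(small_cfg)
    batches = simulate_reads(genomes, truth, small_cfg)
    return small_cfg, genomes, truth, batches


@pytest.fixture(scope="session")
def clean_cfg():
    """Error-free, divergence-free single-organism config."""
    return SimulationConfig(
        seed=3,
        pathogen_genome_len=5_000,
        host_genome_len=10_000,
        n_genes_host=20,
        n_genes_pathogen=10,
        timepoints=("0h",),
        pathogen_read_fraction=(0.0,),
        replicates_per_timepoint=1,
        reads_per_sample=400,
        snp_divergence_rate=0.0,
        indel_divergence_rate=0.0,
        base_error_rate=0.0,
        quality_model=QualityModel(tail_prob=0.0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
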