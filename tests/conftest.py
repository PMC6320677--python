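import dendropy
import numpy as np
import pandas as pd
import pytest

from cladeforge.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def quartet_dataset():
    """A 4-species dataset without introgression, reused across tests."""
    cfg = SimulationConfig(
        seed=42,
        n_species=4,
        n_genes=10,
        codons_per_gene=100,
        n_snp_sites=1500,
        n_indel_events=400,
        n_orthogroups=50,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def three_taxon_tree():
    return dendropy.Tree.get(data="((A:1.0,B:1.0):1.0,C:2.0);", schema="newick")


@pytest.fixture
def snp_frame(quartet_dataset):
    return pd.DataFrame(quartet_dataset.variants["snps"])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
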