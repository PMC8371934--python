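import numpy as np
import pytest

from sesaqtl import binning, genmap
from sesaqtl.simdata import QTLSpec, SimConfig, simulate_f2


def single_trait_config(**kw) -> SimConfig:
    """One-trait SimConfig helper with unit-variance phenotype scale."""
    defaults = dict(
        n_chromosomes=1, chrom_length_cM=100.0, marker_density=2.0,
        qtl_spec={"L": [QTLSpec(1, 45.0, 1.0, 0.0, 0.40)]},
        trait_corr=np.array([[1.0]]),
        trait_means={"L": 0.0}, trait_sds={"L": 1.0}, seed=0)
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_cross():
    """A 2-chromosome, 120-individual cross with default noise and one
    strong QTL, shared read-only across tests."""
    cfg = single_trait_config(n_chromosomes=2, seed=42)
    truth, obs, pheno = simulate_f2(cfg)
    return cfg, truth, obs, pheno


@pytest.fixture(scope="session")
def small_map(small_cross):
    """Spaced genetic map built from the shared cross."""
    _, _, obs, _ = small_cross
    bins = binning.make_bin_map(obs)
    gmap = genmap.group_bins(bins, min_group_size=10)
    return genmap.space_map(gmap)
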