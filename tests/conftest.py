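import pytest

import droughtmet as dm


@pytest.fixture(scope="session")
def full_sim():
    """Full 390-sample design with planted osmoprotectants, DNB and outliers."""
    cfg = dm.SimulationConfig(seed=11, n_metabolites=25)
    abund, meta, truth = dm.simulate_dataset(cfg)
    return cfg, abund, meta, truth


@pytest.fixture(scope="session")
def logged_full(full_sim):
    _, abund, meta, _ = full_sim
    logged = dm.log_transform(dm.normalize(abund, meta, "Ribitol"))
    return logged, meta


@pytest.fixture(scope="session")
def deep_replicate_sim():
    """Single genotype/tissue with 20 replicates per point: correlation-based
    statistics (DNB) need more than the 5 study replicates to be stable."""
    cfg = dm.SimulationConfig(
        seed=23, n_metabolites=40, genotypes=("WT",), tissues=("root",),
        replicates=tuple(range(1, 21)), outliers=None,
    )
    abund, meta, truth = dm.simulate_dataset(cfg)
    logged = dm.log_transform(dm.normalize(abund, meta, "Ribitol"))
    return logged, meta, truth
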