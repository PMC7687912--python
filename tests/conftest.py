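import numpy as np
import pytest

from ernarch.simulate import (
    SimConfig,
    simulate_genotypes,
    simulate_procap,
    simulate_truth,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort shared by read-only tests."""
    cfg = SimConfig(n_individuals=30, n_ttres=30, n_variants=600,
                    genome_length=300_000, n_ti_qtls=8, n_di_qtls=8,
                    n_e_qtls=4, seed=7)
    rng = cfg.rng()
    genotypes = simulate_genotypes(cfg, rng)
    truth = simulate_truth(cfg, genotypes, rng)
    signals = simulate_procap(cfg, genotypes, truth, rng)
    return cfg, genotypes, truth, signals


@pytest.fixture
def rng():
    return np.random.default_rng(42)
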