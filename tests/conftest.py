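import numpy as np
import pytest

from tetramap.simdata import SimConfig, simulate_f1, simulate_parents


@pytest.fixture(scope="session")
def small_cross():
    """One simulated chromosome, clean data, maternal simplex markers only."""
    cfg = SimConfig(n_chromosomes=1, n_markers_per_chrom=50, n_offspring=187,
                    seed=101, seg_mix={"1x0": 1.0})
    mother, father = simulate_parents(cfg)
    matrix, truth = simulate_f1(mother, father, cfg)
    return cfg, mother, father, matrix, truth


@pytest.fixture(scope="session")
def mixed_cross():
    """Two chromosomes with the default segregation mix and light noise."""
    cfg = SimConfig(n_chromosomes=2, n_markers_per_chrom=80, n_offspring=187,
                    seed=202, co_rate=2.8, dosage_error_rate=0.01,
                    missing_rate=0.02,
                    seg_mix={"1x0": 0.3, "0x1": 0.3, "1x1": 0.4})
    mother, father = simulate_parents(cfg)
    matrix, truth = simulate_f1(mother, father, cfg)
    return cfg, mother, father, matrix, truth


@pytest.fixture
def rng():
    return np.random.default_rng(7)
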