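import numpy as np
import pytest

from mofsync.simulate import PlantedEffect, SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_null_cohort():
    """30 eligible patients, no planted effects, dense sampling around the peak."""
    config = SimulationConfig(
        n_patients=30,
        sex_ratio=0.5,
        n_genes=400,
        n_gene_sets=20,
        set_size_range=(5, 15),
        acute_day_range=(4, 4),
        sampling_days=(1, 2, 3, 4, 5, 6, 7),
        plateau_prob=0.0,
        frac_sex_chrom_genes=0.0,
        seed=42,
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def planted_cohort():
    """60 patients with one up-in-female acute set and one down-in-female pre-acute set."""
    config = SimulationConfig(
        n_patients=60,
        sex_ratio=0.5,
        n_genes=800,
        n_gene_sets=30,
        set_size_range=(5, 20),
        acute_day_range=(4, 4),
        sampling_days=(1, 2, 3, 4, 5, 6, 7),
        planted_effects=[
            PlantedEffect("SET_0000", "acute", "up_in_female", 1.0),
            PlantedEffect("SET_0001", "pre_acute", "down_in_female", 1.0),
        ],
        plateau_prob=0.2,
        seed=7,
    )
    return simulate_cohort(config)
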