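import numpy as np
import pytest

from admixcohort import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort with every nuisance switched on (shared, read-only)."""
    cfg = SimulationConfig(
        n_samples={"grpA": 40, "grpB": 40},
        m_variants=400,
        n_chromosomes=2,
        k_true=2,
        fst=(0.15, 0.15),
        alpha={"grpA": (4.0, 1.0), "grpB": (1.0, 4.0)},
        missing_rate=0.02,
        diff_missing=("diabetes", 0.2, 0.1),
        batch_distortion=(2, 10, 0.3),
        n_duplicates=2,
        n_parent_child_pairs=1,
        sex_mismatch_rate=0.03,
        x_variants=60,
        beta_age=0.1,
        beta_sex=0.1,
        causal_snps=((5, 0.3),),
        seed=1234,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_two_pop():
    """Clean two-population admixed cohort (no nuisances)."""
    cfg = SimulationConfig(n_samples=200, m_variants=1500, n_chromosomes=2,
                           k_true=2, fst=(0.2, 0.2), alpha=(0.5, 0.5),
                           seed=77)
    return cfg, simulate_cohort(cfg)
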