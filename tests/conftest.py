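import numpy as np
import pandas as pd
import pytest

from teatqtl.cohort import CohortConfig, simulate_cohort


def small_cohort_config(seed: int = 11) -> CohortConfig:
    """Scaled-down cohort for fast unit tests (structure, not power)."""
    return CohortConfig(
        seed=seed,
        n_founders=80,
        n_generations=2,
        n_farms=4,
        n_sires_per_generation=8,
        n_dams_per_generation=30,
        n_snps=420,
        n_chromosomes=3,
        n_unmapped_snps=6,
        n_low_call_rate_snps=4,
        n_genotyped_young=120,
        qtl_variance_shares=(0.15, 0.10),
    )


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_cohort_config())


@pytest.fixture(scope="session")
def tiny_bvs_data():
    """n=20, p=3 instance small enough for exhaustive posterior enumeration."""
    rng = np.random.default_rng(5)
    n, p = 20, 3
    X = rng.integers(0, 3, size=(n, p)).astype(float)
    w = rng.uniform(0.5, 2.0, n)
    y = X @ np.array([0.5, 0.0, -0.3]) + rng.normal(0, 1 / np.sqrt(w))
    y = y - y.mean()
    return y, X, w
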