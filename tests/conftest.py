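import numpy as np
import pytest

from prrtdose import CohortConfig, DoseFactorTable, generate_cohort

CYCLES = (1, 2, 3, 4)


@pytest.fixture(scope="session")
def factors():
    return DoseFactorTable()


@pytest.fixture(scope="session")
def small_cohort():
    """Six noisy patients, enough for integration paths without long fits."""
    cfg = CohortConfig(n_patients=6, rng_seed=7, n_missing_blood=1)
    truths, series = generate_cohort(cfg)
    return cfg, truths, series


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Three patients with zero measurement noise for exact-recovery checks."""
    cfg = CohortConfig(n_patients=3, rng_seed=11, noise_cv=0.0,
                       n_missing_blood=0)
    truths, series = generate_cohort(cfg)
    return cfg, truths, series


def activities_of(truths):
    return {(t.patient_id, c): t.activities_gbq[c - 1]
            for t in truths for c in CYCLES}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
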