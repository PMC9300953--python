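import numpy as np
import pytest

from sighub.synthetic import CohortParams, generate_cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """One medium planted-hub cohort shared by read-only tests."""
    params = CohortParams(n_samples=300, n_genes=500, n_partners=12,
                          rho_high=0.5, rho_low=0.05, beta=1.0,
                          censor_frac=0.3, rng_seed=3)
    expr, clinical, annotation, truth = generate_cohort(params)
    return params, expr, clinical, annotation, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20220707)
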