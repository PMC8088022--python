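import pytest

from rehrval.simulate import MSCohortParams, PCaCohortParams, simulate_ms_cohort, simulate_pca_cohort


@pytest.fixture(scope="session")
def ms_cohort_noisy():
    """Default study conditions: imperfect emission plus background noise."""
    params = MSCohortParams(n_patients=300, seed=101)
    return simulate_ms_cohort(params)


@pytest.fixture(scope="session")
def ms_cohort_noiseless():
    """Perfect care-pathway emission, zero noise: the algorithm should be exact."""
    params = MSCohortParams(
        n_patients=300,
        p_steroid_given_relapse=1.0,
        p_hospital_given_relapse=1.0,
        noise_steroid_rate_per_year=0.0,
        noise_hospital_rate_per_year=0.0,
        seed=77,
    )
    return simulate_ms_cohort(params)


@pytest.fixture(scope="session")
def pca_cohort():
    params = PCaCohortParams(n_patients=300, seed=55)
    return simulate_pca_cohort(params)
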