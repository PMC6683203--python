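import numpy as np
import pytest
from hypothesis import settings

import sublethal as sl

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def ref_params() -> sl.ParameterSet:
    """Published posterior means with the generator's default scales."""
    return sl.reference_parameters()


@pytest.fixture(scope="session")
def published_design() -> sl.CohortDesign:
    """The original experiment's sizes: 245 / 14x4 / 842."""
    return sl.CohortDesign()


@pytest.fixture(scope="session")
def small_design() -> sl.CohortDesign:
    """A reduced split-brood design for fast fitting tests."""
    return sl.CohortDesign(n_gen1_larvae=150, n_sires=4, dams_per_sire=4,
                           n_gen2_larvae=240, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_design, ref_params):
    """A simulated small two-generation cohort, as a frame."""
    individuals, families = sl.simulate_cohort(small_design, ref_params,
                                               seed=7)
    return sl.cohort_to_frame(individuals)


@pytest.fixture(scope="session")
def published_cohort(published_design, ref_params):
    """One cohort at the published sample sizes."""
    individuals, families = sl.simulate_cohort(published_design, ref_params,
                                               seed=1)
    return sl.cohort_to_frame(individuals)


@pytest.fixture(scope="session")
def small_survival_fit(small_cohort):
    """A quick survival-blocks posterior on the small cohort."""
    cfg = sl.McmcConfig(burn_in=4000, keep=500, thin=4, seed=21)
    return sl.sample_posterior(small_cohort, sl.survival_specs(), config=cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
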