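"""Shared fixtures: canonical paradigm objects and the two expensive fits.

The hierarchical fits are session-scoped so that module-level tests and the
acceptance suite reuse the same posterior instead of re-sampling.
All seeds are fixed constants.
"""

import warnings

import numpy as np
import pytest

from ergochoice.agents import (
    default_study_cohort,
    model_recovery_cohorts,
    sample_cohort,
    simulate_study,
)
from ergochoice.estimation import McmcConfig, fit_isoelastic_hierarchical
from ergochoice.paradigm import Dynamic, build_active_session, make_stimulus_set
from ergochoice.selection import fit_hlm

STUDY_COHORT_SEED = 11
STUDY_CHOICE_SEED = 12
STUDY_MCMC_SEED = 13
RECOVERY_COHORT_SEED = 21
RECOVERY_CHOICE_SEED = 24
RECOVERY_MCMC_SEED = 25
SESSION_SEED = 100


@pytest.fixture(scope="session")
def stimulus_sets():
    return {d: make_stimulus_set(d) for d in Dynamic}


@pytest.fixture(scope="session")
def sessions(stimulus_sets):
    return {d: build_active_session(stimulus_sets[d], seed=SESSION_SEED)
            for d in Dynamic}


@pytest.fixture(scope="session")
def study_cohort():
    """The synthetic study replica: 18 time-optimal agents."""
    return sample_cohort(default_study_cohort(), seed=STUDY_COHORT_SEED)


@pytest.fixture(scope="session")
def study_data(study_cohort, sessions):
    return simulate_study(study_cohort, sessions, seed=STUDY_CHOICE_SEED)


@pytest.fixture(scope="session")
def study_fit(study_data):
    """Hierarchical isoelastic fit of the 18-agent study replica."""
    return fit_isoelastic_hierarchical(
        study_data,
        cfg=McmcConfig(n_chains=4, n_draws=2000, n_burnin=500,
                       seed=STUDY_MCMC_SEED),
    )


@pytest.fixture(scope="session")
def recovery_cohorts():
    """Three 9-agent cohorts (TIME, PT, ISO) and their pooled dataset."""
    specs = model_recovery_cohorts(9)
    agents = []
    for i, spec in enumerate(specs.values()):
        agents += sample_cohort(spec, seed=RECOVERY_COHORT_SEED + i)
    data = simulate_study(agents, seed=RECOVERY_CHOICE_SEED)
    return specs, data


@pytest.fixture(scope="session")
def recovery_hlm(recovery_cohorts):
    """Latent-mixture fit of the pooled 27-agent model-recovery dataset."""
    _, data = recovery_cohorts
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_hlm(data, cfg=McmcConfig(n_chains=2, n_draws=2000,
                                            n_burnin=500,
                                            seed=RECOVERY_MCMC_SEED))
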