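import numpy as np
import pytest

from ugtphen import DoseEvent, StructuralParams, simulate_profile
from ugtphen.population import (PopulationModel, apply_residual_error,
                                sample_individuals)

#: Published final-model estimates used as generative truth throughout.
TABLE2_THETA = dict(cl_f=41.7, v_f=157.0, ka=4.23, mtt=1.04, nn=1.07,
                    f=1.0, fmet=0.0324, cl_glu=0.715, v_glu=1.0)
TABLE2_OMEGA_CV = {"cl_f": 30.5, "v_f": 81.4, "mtt": 107.2, "f": 123.7,
                   "fmet": 37.7, "cl_glu": 13.6}
TABLE2_CORR = 0.57
TABLE2_SIGMA = {"sigma_ral": 0.15, "sigma_glu": 0.18}


@pytest.fixture(scope="session")
def theta() -> StructuralParams:
    return StructuralParams(**TABLE2_THETA)


@pytest.fixture(scope="session")
def pop_model(theta) -> PopulationModel:
    return PopulationModel(theta, omega_cv=dict(TABLE2_OMEGA_CV),
                           corr_cl_v=TABLE2_CORR, **TABLE2_SIGMA)


@pytest.fixture(scope="session")
def single_dose():
    return [DoseEvent(0.0, 400.0)]


def _simulate_cohort_data(pop, n, times, seed, dose=400.0):
    """Simulate (parent, metabolite) profile pairs with residual error."""
    rng = np.random.default_rng(seed)
    inds = sample_individuals(pop, n, rng)
    doses = [DoseEvent(0.0, dose)]
    data = []
    for ind in inds:
        p, m = simulate_profile(ind.params, doses, times,
                                subject_id=ind.subject_id)
        data.append((apply_residual_error(p, pop.sigma_ral, rng),
                     apply_residual_error(m, pop.sigma_glu, rng)))
    return inds, data


@pytest.fixture(scope="session")
def simulate_cohort_data():
    return _simulate_cohort_data
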