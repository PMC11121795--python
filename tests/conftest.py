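import warnings

import numpy as np
import pytest

from exogem.model import set_biomass_floor
from exogem.resos import run_resos
from exogem.sampling import sample_fluxes
from exogem.synthetic import (
    CohortSpec,
    GroupEffect,
    make_toy_model,
    simulate_cohort,
    toy_metabolite_map,
    toy_tasks,
)


@pytest.fixture(scope="session")
def toy_model():
    return make_toy_model()


@pytest.fixture(scope="session")
def floored_model(toy_model):
    return set_biomass_floor(toy_model, 0.5)


@pytest.fixture(scope="session")
def baseline_samples(floored_model):
    """2000 baseline samples shared by the slower integration tests."""
    return sample_fluxes(floored_model, 2000, seed=1, thinning=5)


@pytest.fixture(scope="session")
def baseline_resos(baseline_samples):
    scores, result = run_resos(baseline_samples)
    return scores, result


@pytest.fixture(scope="session")
def small_cohort():
    """4 groups x 2 patients, moderate planted effects, toy metabolite map."""
    names = list(toy_metabolite_map().keys())
    spec = CohortSpec(
        n_groups=4,
        patients_per_group=2,
        n_controls=10,
        n_metabolites=len(names),
        metabolite_names=names,
        control_log_sd=0.05,
        effects={
            "B": [GroupEffect(["met_r", "met_q"], 0.2)],
            "C": [GroupEffect(["met_a", "met_p"], 0.2)],
            "D": [GroupEffect(["met_a", "met_o", "met_n", "met_s"], 3.0)],
        },
        seed=7,
    )
    return simulate_cohort(spec, metabolite_map=toy_metabolite_map())


@pytest.fixture(scope="session")
def example_tasks():
    return toy_tasks()


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        yield
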