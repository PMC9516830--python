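"""Shared fixtures: one mid-sized simulated site reused across test modules."""

import pytest

from gravida.features import build_code_count_matrix, build_gestational_cohort
from gravida.phenotype import AscertainmentCodeSets, phenotype_cohort
from gravida.simulate import default_config, simulate_cohort


@pytest.fixture(scope="session")
def code_sets():
    return AscertainmentCodeSets.default()


@pytest.fixture(scope="session")
def sim():
    """Default-conditions site-A cohort, 2,500 patients."""
    return simulate_cohort(default_config(n_patients=2500, seed=11))


@pytest.fixture(scope="session")
def first_truth(sim):
    return sim.truth[sim.truth["pregnancy_index"] == 1].set_index("patient_id")


@pytest.fixture(scope="session")
def episodes(sim, code_sets):
    return phenotype_cohort(sim.code_events, sim.ega, code_sets)


@pytest.fixture(scope="session")
def cohort28(episodes):
    return build_gestational_cohort(episodes, 28)


@pytest.fixture(scope="session")
def fm28(sim, cohort28, code_sets):
    return build_code_count_matrix(sim.code_events, cohort28, code_sets)
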