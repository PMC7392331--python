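import numpy as np
import pytest

import bwspref as b
from bwspref import uganda


@pytest.fixture(scope="session")
def catalogue16():
    return uganda.CATALOGUE


@pytest.fixture(scope="session")
def design16(catalogue16):
    """Survey-shaped design: 16 tasks of 4 sectors, 4 appearances each."""
    return b.generate_design(catalogue16, k=4, T=16, seed=1)


@pytest.fixture(scope="session")
def small_design():
    """Tiny instance for enumeration oracles: J=4 items, k=3, T=4."""
    return b.generate_design(4, k=3, T=4, seed=3)


def make_scenario(design, utilities, n=200, sigma=0.0, seed=0, label="all"):
    return b.SimulationScenario(
        catalogue=design.catalogue,
        design=design,
        strata=[b.Stratum(label, n, np.asarray(utilities, float))],
        heterogeneity_sd=sigma,
        seed=seed,
    )


@pytest.fixture(scope="session")
def survey_scenario(design16):
    """Survey-shaped single-stratum scenario with the published logit
    estimates as true utilities."""
    return make_scenario(
        design16, uganda.clogit_utilities(), n=432, seed=11
    )


@pytest.fixture(scope="session")
def simulated_responses(survey_scenario):
    return b.simulate_responses(survey_scenario)
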