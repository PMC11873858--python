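"""Shared fixtures.

The heavy generate-and-refit studies are session-scoped so that every
acceptance check reuses one set of fits.
"""

import numpy as np
import pytest

import rmmtree as rt


@pytest.fixture(scope="session")
def space():
    return rt.CategorySpace(4)


@pytest.fixture(scope="session")
def small_items():
    return rt.generate_item_bank(5, nr_rate=0.2, seed=101)


@pytest.fixture(scope="session")
def small_data(small_items, space):
    persons = rt.generate_person_bank(80, seed=102)
    data, z = rt.generate_responses(persons, small_items, space, seed=103)
    return persons, data, z


@pytest.fixture(scope="session")
def study_nr20():
    """10-replication recovery study at N=1000, K=50, 20% NR (RMM + GRM)."""
    design = rt.SimulationDesign(
        n_persons=1000, n_items=50, nr_rate=0.2, n_replications=10, seed=1
    )
    return rt.run_simulation_study(design)


@pytest.fixture(scope="session")
def grm_study_nr0():
    """GRM-only 10-replication study on mixture-free (0% NR) data."""
    design = rt.SimulationDesign(
        n_persons=1000, n_items=50, nr_rate=0.0, n_replications=10, seed=1
    )
    return rt.run_simulation_study(design, models=("grm",))


@pytest.fixture(scope="session")
def rmm_fit_medium(space):
    """One RMM fit on N=1000, K=25, 20%-NR data with known truth."""
    items = rt.generate_item_bank(25, nr_rate=0.2, seed=201)
    persons = rt.generate_person_bank(1000, seed=202)
    data, z = rt.generate_responses(persons, items, space, seed=203)
    samples = rt.fit(
        data, config=rt.ChainConfig(1500, 300, 2, seed=204, model="rmm")
    )
    return persons, items, data, z, samples
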