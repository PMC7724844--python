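import numpy as np
import pandas as pd
import pytest

from plucksim import scenarios
from plucksim.cart import CartRegressor
from plucksim.synthetic_cohort import LESION_COLUMNS, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default 56-farm synthetic cohort, master seed 0."""
    return generate_cohort(scenarios.DEFAULT_CLUSTERS, seed=0)


@pytest.fixture(scope="session")
def fitted_tree(cohort):
    """Cross-validated, pruned regression tree on the default cohort."""
    model = CartRegressor(min_leaf=10, k_folds=10, random_state=0)
    model.fit(cohort[LESION_COLUMNS], cohort["adg"])
    return model


@pytest.fixture(scope="session")
def lplsc():
    return scenarios.default_scenario("LPLSC")


@pytest.fixture(scope="session")
def all_scenarios():
    return scenarios.default_scenarios()
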