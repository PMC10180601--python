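import warnings

import numpy as np
import pytest

from dendrostress import climate_index_table, simulate_climate, simulate_forest
from dendrostress.synthetic import (
    DEFAULT_DROUGHTS,
    ClimateGenConfig,
    ForestGenConfig,
)


@pytest.fixture(scope="session")
def study_climate():
    """26-year daily climate with the default engineered drought years."""
    cfg = ClimateGenConfig(seed=11, drought_years=dict(DEFAULT_DROUGHTS))
    return simulate_climate(cfg)


@pytest.fixture(scope="session")
def study_index_table(study_climate):
    years = np.unique(study_climate.index.year)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return climate_index_table(study_climate, years)


@pytest.fixture(scope="session")
def cedar_forest(study_climate):
    """20-tree forest driven by current February precipitation."""
    cfg = ForestGenConfig(
        species="CED", n_trees=20, seed=7,
        driver=("ppt", "FEB"),
        drought_multipliers={2003: 0.75, 2012: 0.80, 2015: 0.95, 2018: 0.95},
    )
    return simulate_forest(cfg, study_climate)
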