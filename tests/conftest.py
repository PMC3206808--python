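import numpy as np
import pandas as pd
import pytest

from reefmarkov import ReefMarkovModel, StateScheme, datasets


@pytest.fixture(scope="session")
def scheme():
    return StateScheme()


@pytest.fixture(scope="session")
def caribbean():
    return datasets.load_caribbean_counts()


@pytest.fixture(scope="session")
def gbr():
    return datasets.load_gbr_counts()


@pytest.fixture(scope="session")
def caribbean_fit(caribbean):
    return ReefMarkovModel(caribbean).fit()


@pytest.fixture(scope="session")
def gbr_fit(gbr):
    return ReefMarkovModel(gbr).fit()


@pytest.fixture()
def toy_surveys():
    """Small hand-built survey table with replicates, a gap year, and metadata."""
    return pd.DataFrame(
        {
            "reef": ["R1", "R1", "R1", "R1", "R2", "R2", "R3"],
            "year": [2004, 2004, 2005, 2006, 2004, 2006, 2005],
            "coral": [20.0, 40.0, 10.0, 15.0, 60.0, 55.0, 30.0],
            "algae": [10.0, 30.0, 40.0, 30.0, 20.0, 10.0, 60.0],
            "mpa": [True, True, True, True, False, False, None],
            "region": ["X"] * 7,
        }
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20111102)
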