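import numpy as np
import pandas as pd
import pytest

from altinull import (CommunityMatrix, DistrictConfig, SiteTable, generate_lakes)


@pytest.fixture(scope="session")
def survey_sites() -> SiteTable:
    """A default-sized synthetic district: 82 lakes, 1620-2990 m,
    mid-concentrated, with the standard environmental variable bank."""
    return generate_lakes(DistrictConfig(seed=20000))


@pytest.fixture(scope="session")
def survey_altitudes(survey_sites) -> np.ndarray:
    return survey_sites.altitude.to_numpy()


@pytest.fixture
def toy_sites() -> SiteTable:
    df = pd.DataFrame(
        {"altitude": [1620.0, 2000.0, 2200.0, 2400.0, 2990.0]},
        index=pd.Index([f"L{i}" for i in range(5)], name="site_id"),
    )
    return SiteTable(df)


@pytest.fixture
def toy_community(toy_sites) -> CommunityMatrix:
    counts = pd.DataFrame(
        {
            "spA": [1, 0, 3, 0, 0],
            "spB": [2, 1, 1, 4, 1],
            "spC": [0, 0, 0, 0, 5],
        },
        index=toy_sites.data.index,
    )
    return CommunityMatrix("toy", counts)


def random_community(rng: np.random.Generator, n_sites: int = 10, n_species: int = 8,
                     max_count: int = 5) -> CommunityMatrix:
    counts = rng.integers(0, max_count + 1, size=(n_sites, n_species))
    return CommunityMatrix(
        "rand",
        pd.DataFrame(
            counts,
            index=pd.Index([f"L{i}" for i in range(n_sites)], name="site_id"),
            columns=[f"sp{j}" for j in range(n_species)],
        ),
    )
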