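"""Shared fixtures: species parameters, historical census counts and
synthetic landscapes (session-scoped where generation is not free)."""

import numpy as np
import pandas as pd
import pytest

from rangecap import (
    LandscapeConfig,
    default_species_profiles,
    default_wildlife_profiles,
    generate_field_campaign,
    generate_grazing_system,
    generate_landscape,
)
from rangecap.energy_demand import SeasonCalendar

# Published Big Pamir livestock census (head counts, summer/winter) used as
# a real-world fixture for the herd-size accounting; camels enter in 2016.
CENSUS_YEARS = (2006, 2010, 2011, 2012, 2013, 2014, 2015, 2016, 2017, 2018, 2019, 2020)
HISTORICAL_COUNTS = {
    "goat": {
        "summer": (1059, 3663, 4054, 3886, 4982, 5490, 5151, 4547, 4555, 5349, 4801, 5596),
        "winter": (205, 451, 438, 413, 722, 350, 504, 770, 770, 917, 760, 875),
    },
    "sheep": {
        "summer": (6525, 8101, 7344, 8046, 11017, 10093, 10306, 9187, 9033, 9321, 8110, 9576),
        "winter": (1017, 1070, 938, 1023, 1404, 3177, 3966, 4295, 4295, 2070, 1871, 2214),
    },
    "yak": {
        "summer": (683, 905, 949, 915, 1081, 936, 966, 907, 978, 764, 726, 849),
        "winter": (106, 114, 102, 86, 118, 145, 233, 205, 205, 138, 123, 146),
    },
    "cattle": {
        "summer": (982,) * 12,
        "winter": (0,) * 12,
    },
    "camel": {
        "summer": (None, None, None, None, None, None, None, 30, 30, 17, 31, 22),
        "winter": (None, None, None, None, None, None, None, 0, 0, 0, 0, 0),
    },
}
SLU_TOTALS = {
    "summer": (12579, 17425, 17191, 17623, 22188, 21337, 21301, 19491, 19558, 19959, 18128, 20731),
    "winter": (1540, 1863, 1682, 1694, 2480, 3962, 5169, 5680, 5680, 3401, 3000, 3527),
}


def historical_census() -> pd.DataFrame:
    rows = []
    for species, by_season in HISTORICAL_COUNTS.items():
        for season, counts in by_season.items():
            for year, n in zip(CENSUS_YEARS, counts):
                if n is None:
                    continue
                rows.append(
                    {
                        "year": year,
                        "season": season,
                        "area_id": "region",
                        "species": species,
                        "age_class": "adult",
                        "count": n,
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def census_history() -> pd.DataFrame:
    return historical_census()


@pytest.fixture(scope="session")
def profiles():
    return default_species_profiles()


@pytest.fixture(scope="session")
def wildlife_profiles():
    return default_wildlife_profiles()


@pytest.fixture(scope="session")
def calendar():
    return SeasonCalendar()


@pytest.fixture(scope="session")
def small_config():
    return LandscapeConfig(n_rows=120, n_cols=120, seed=7)


@pytest.fixture(scope="session")
def small_landscape(small_config):
    return generate_landscape(small_config)


@pytest.fixture(scope="session")
def small_areas(small_config):
    return generate_grazing_system(small_config)


@pytest.fixture(scope="session")
def small_campaign(small_landscape):
    return generate_field_campaign(small_landscape)


@pytest.fixture(scope="session")
def default_config():
    return LandscapeConfig(seed=0)


@pytest.fixture(scope="session")
def default_landscape(default_config):
    return generate_landscape(default_config)


@pytest.fixture(scope="session")
def default_areas(default_config):
    return generate_grazing_system(default_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
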