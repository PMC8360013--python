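import numpy as np
import pandas as pd
import pytest

from riversdm import pipeline, synthetic


@pytest.fixture(scope="session")
def small_riverscape():
    return synthetic.generate_riverscape(120, seed=42)


@pytest.fixture(scope="session")
def true_X(small_riverscape):
    return synthetic.true_predictor_matrix(small_riverscape)


@pytest.fixture(scope="session")
def species_pool(true_X):
    ranges = pipeline._niche_ranges(true_X, ("water_temp_mean", "discharge_logmean", "forest"))
    return synthetic.generate_species_pool(12, seed=7, niche_ranges=ranges)


@pytest.fixture(scope="session")
def surveys(small_riverscape, species_pool, true_X):
    return synthetic.simulate_surveys(
        small_riverscape,
        species_pool,
        80,
        {"species": 0.85, "genus": 0.10, "family": 0.05},
        seed=11,
        predictors=true_X,
    )


def make_survey_records(rows):
    """rows: (site_id, date, taxon, rank, genus, family) tuples."""
    return pd.DataFrame(
        rows, columns=["site_id", "date", "taxon", "rank", "genus", "family"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
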