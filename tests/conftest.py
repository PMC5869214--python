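import numpy as np
import pandas as pd
import pytest

from andrias import (
    LandscapeConfig,
    RasterGrid,
    SurveyConfig,
    generate_interviews,
    generate_landscape,
)
from andrias.interviews import normalize_records, summarize_counties


@pytest.fixture(scope="session")
def small_landscape():
    cfg = LandscapeConfig(
        grid_rows=60, grid_cols=60, n_counties=24, n_provinces=6, seed=7
    )
    return cfg, generate_landscape(cfg)


@pytest.fixture(scope="session")
def survey_design():
    """24 counties in 6 provinces, both arms present in most provinces."""
    rng = np.random.default_rng(5)
    prov = np.repeat(np.arange(1, 7), 4)
    method = np.tile([0, 1, 0, 1], 6)
    return pd.DataFrame(
        {
            "county_id": np.arange(1, 25),
            "province": prov,
            "selection_method": method,
        }
    )


@pytest.fixture(scope="session")
def interview_dataset(survey_design):
    cfg = SurveyConfig(respondents_per_county=30, effect_prob=0.05, seed=11)
    records, truth = generate_interviews(survey_design, cfg)
    records = normalize_records(records)
    return records, truth


@pytest.fixture(scope="session")
def county_summaries(interview_dataset):
    records, _ = interview_dataset
    return summarize_counties(records)


def make_grid(values, nodata=-9999.0, **kw):
    return RasterGrid(np.asarray(values, dtype=float), nodata=nodata, **kw)
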