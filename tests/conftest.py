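import numpy as np
import pytest
from hypothesis import settings

from arabica_sdm import (GridSpec, TrueNiche, default_scenarios, deduplicate,
                         generate_baseline, generate_future,
                         make_survey_fixture, sample_occurrences,
                         true_suitability)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

# the default study niche: strong and narrow, at the cool/wet margin of the
# regional climate space, so every scenario perturbation erodes it
STRONG_NICHE = TrueNiche(
    optima={"temp_seasonality": 42.5, "temp_warmest_quarter": 16.2,
            "precip_driest_month": 60.0, "temp_wettest_quarter": 13.2},
    tolerances={"temp_seasonality": 3.6, "temp_warmest_quarter": 1.08,
                "precip_driest_month": 7.2, "temp_wettest_quarter": 1.08})


@pytest.fixture(scope="session")
def grid50():
    return GridSpec(n_rows=50, n_cols=50, cell_size=0.02,
                    origin_lon=35.0, origin_lat=8.0)


@pytest.fixture(scope="session")
def grid100():
    return GridSpec(n_rows=100, n_cols=100, cell_size=0.02,
                    origin_lon=35.0, origin_lat=8.0)


@pytest.fixture(scope="session")
def baseline50(grid50):
    return generate_baseline(grid50, n_layers=4, autocorrelation_length=5.0, seed=7)


@pytest.fixture(scope="session")
def baseline100(grid100):
    return generate_baseline(grid100, n_layers=4, autocorrelation_length=5.0, seed=0)


@pytest.fixture(scope="session")
def strong_niche():
    return STRONG_NICHE


@pytest.fixture(scope="session")
def suitability100(baseline100, strong_niche):
    return true_suitability(baseline100, strong_niche)


@pytest.fixture(scope="session")
def scenario_stacks50(baseline50):
    """Baseline + 9 future stacks (3 scenarios x 3 dates)."""
    stacks = [baseline50]
    for spec in default_scenarios():
        if not spec.is_baseline:
            stacks.append(generate_future(baseline50, spec))
    return stacks


@pytest.fixture(scope="session")
def survey_records(grid50, baseline50, strong_niche):
    """719 raw records with the historical cleaning-chain count structure."""
    suit = true_suitability(baseline50, strong_niche)
    return make_survey_fixture(grid50, suitability=suit, seed=3)


@pytest.fixture(scope="session")
def presence_background100(grid100, baseline100, suitability100):
    """(presence_env, background_env, presence_points) for recovery tests."""
    records = sample_occurrences(suitability100, 200, clustering=0.0,
                                 frac_bad=0.0, seed=1)
    localities = deduplicate(records)
    pts = np.array([(l.lon, l.lat) for l in localities])
    rc = [grid100.cell_index(x, y) for x, y in pts]
    rows = np.array([r for r, _ in rc])
    cols = np.array([c for _, c in rc])
    presence_env = baseline100.env_matrix(rows, cols)
    rr, cc = np.nonzero(~baseline100.mask)
    background_env = baseline100.env_matrix(rr, cc)
    return presence_env, background_env, pts
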