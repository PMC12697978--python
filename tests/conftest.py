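import numpy as np
import pandas as pd
import pytest

from frontiergap import LifePanel, SyntheticConfig, generate
from frontiergap.panel_io import SUPPORTED_AGES


def make_panel_df(values, year=2019):
    """Build a long panel DataFrame from {location: {sex: {age: ex}}}."""
    rows = []
    for loc, by_sex in values.items():
        for sex, by_age in by_sex.items():
            for age, ex in by_age.items():
                rows.append({"location": loc, "year": year, "sex": sex,
                             "age": age, "ex": ex})
    return pd.DataFrame(rows)


def flat_panel(n_locations, lf, lm, year=2019, ages=(0,)):
    """Panel where every location has female ex=lf, male ex=lm at all ages."""
    values = {f"loc{i:02d}": {"female": {a: lf for a in ages},
                              "male": {a: lm for a in ages}}
              for i in range(n_locations)}
    return LifePanel(make_panel_df(values, year=year))


def random_panel(rng, n_locations, year=2019, ages=(0,)):
    """Random single-year panel with plausible ex values."""
    rows = []
    for i in range(n_locations):
        e0f = rng.uniform(50, 90)
        gap = rng.uniform(-2, 8)
        for age in ages:
            frac = {0: 1.0, 5: 0.95, 15: 0.83, 35: 0.6, 50: 0.43, 70: 0.22}[age]
            rows.append({"location": f"loc{i:03d}", "year": year, "sex": "female",
                         "age": age, "ex": e0f * frac})
            rows.append({"location": f"loc{i:03d}", "year": year, "sex": "male",
                         "age": age, "ex": max(e0f * frac - gap * frac, 1.0)})
    return LifePanel(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def default_panel():
    """Default-condition synthetic panel: 200 locations, 2019, noise 0.5y."""
    return generate(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20190527)


@pytest.fixture
def small_df():
    """2 locations x 1 year x 2 sexes x 6 ages = 24 rows."""
    values = {}
    for loc, e0f, gap in (("Aland", 84.0, 4.0), ("Borduria", 60.0, 5.0)):
        frac = {0: 1.0, 5: 0.95, 15: 0.83, 35: 0.6, 50: 0.43, 70: 0.22}
        values[loc] = {
            "female": {a: e0f * frac[a] for a in SUPPORTED_AGES},
            "male": {a: (e0f - gap) * frac[a] for a in SUPPORTED_AGES},
        }
    return make_panel_df(values)
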