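import numpy as np
import pandas as pd
import pytest

from cfrd.io import RaceTable, merge_events
from cfrd.pipeline import build_panel
from cfrd.synthetic import simulate_default_cohort


def make_table(lap_times: dict, year: int = 2019, category: int = 1) -> RaceTable:
    """Build a RaceTable from {team_id: [lap_time, ...]}."""
    rows = [
        (year, category, team, l + 1, t)
        for team, times in lap_times.items()
        for l, t in enumerate(times)
    ]
    return RaceTable(pd.DataFrame(
        rows, columns=["event_year", "category", "team_id", "lap_index", "lap_time_s"]
    ))


def random_table(rng: np.random.Generator, n_teams: int | None = None,
                 year: int = 2019, category: int = 1,
                 equal_laps: bool = False) -> RaceTable:
    """A random field of <= 25 teams with (optionally unequal) lap counts."""
    if n_teams is None:
        n_teams = int(rng.integers(2, 26))
    laps = {}
    base_laps = int(rng.integers(3, 51))
    for k in range(n_teams):
        n_laps = base_laps if equal_laps else int(rng.integers(1, 51))
        laps[f"team{k:02d}"] = rng.uniform(500, 3000, size=n_laps).tolist()
    return make_table(laps, year=year, category=category)


@pytest.fixture
def toy_table():
    return make_table({"alpha": [100.0, 110.0, 120.0], "beta": [90.0, 95.0, 130.0]})


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_default_cohort(seed=0)


@pytest.fixture(scope="session")
def default_panel(default_cohort):
    return build_panel(default_cohort)


@pytest.fixture(scope="session")
def multiyear_cohort():
    """Four simulated editions merged into one cohort, as in the study."""
    tables = []
    for y in range(4):
        cohort = simulate_default_cohort(seed=1000 + y)
        for t in cohort:
            df = t.df.copy()
            df["event_year"] = 2019 + y
            df["team_id"] = df["team_id"] + f"-y{y}"
            tables.append(RaceTable(df, validate=False))
    return merge_events(tables)


@pytest.fixture(scope="session")
def multiyear_panel(multiyear_cohort):
    return build_panel(multiyear_cohort)
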