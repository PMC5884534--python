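import datetime as dt

import numpy as np
import pandas as pd
import pytest

import occudyn as od


@pytest.fixture(scope="session")
def landscape93():
    return od.simulate_landscape(93, seed=42)


@pytest.fixture(scope="session")
def std_landscape93(landscape93):
    std, scaling = od.standardize(
        landscape93,
        ["elevation", "slope", "dist_coast", "dist_any_water", "dist_freshwater",
         "ground_cover"],
    )
    return std, scaling


@pytest.fixture(scope="session")
def design4():
    return od.default_design()


@pytest.fixture()
def two_station_table():
    return od.StationTable(
        pd.DataFrame(
            {
                "id": ["a", "b"],
                "x": [0.0, 500.0],
                "y": [0.0, 0.0],
                "habitat": ["forest", "meadow"],
                "elevation": [10.0, 20.0],
                "slope": [1.0, 2.0],
                "dist_coast": [100.0, 200.0],
                "dist_any_water": [50.0, 60.0],
                "dist_freshwater": [50.0, 60.0],
                "ground_cover": [30.0, 40.0],
            }
        )
    )


def make_events(station_id, times, day=dt.date(2014, 2, 10)):
    return [
        od.DetectionEvent(
            station_id,
            dt.datetime.combine(day, dt.time()) + dt.timedelta(minutes=m),
        )
        for m in times
    ]


@pytest.fixture()
def intercept_history():
    """Small intercept-only dynamic dataset with known truth (0.6/0.2/0.3/0.5)."""
    rng = np.random.default_rng(123)
    n, n_seasons, k = 80, 3, 4
    z = np.empty((n, n_seasons), int)
    z[:, 0] = rng.random(n) < 0.6
    for t in range(1, n_seasons):
        pr = z[:, t - 1] * 0.7 + (1 - z[:, t - 1]) * 0.2
        z[:, t] = rng.random(n) < pr
    y = (rng.random((n, n_seasons, k)) < z[:, :, None] * 0.5).astype(float)
    X = pd.DataFrame({"id": [f"s{i}" for i in range(n)]})
    return X, y, z
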