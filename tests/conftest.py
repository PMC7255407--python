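import numpy as np
import pytest

import maizegxe as m


@pytest.fixture(scope="session")
def cultivars():
    return m.default_cultivars()


@pytest.fixture(scope="session")
def species():
    return m.default_species()


@pytest.fixture(scope="session")
def ecotype():
    return m.EcotypeParams()


def make_constant_weather(n_days=300, tmax=31.0, tmin=22.0, srad=20.0,
                          rain_every=3, rain_mm=12.0, start="2016-03-01",
                          latitude=11.5):
    """Benign, perfectly regular weather for controlled simulator runs."""
    dates = np.arange(np.datetime64(start, "D"), np.datetime64(start, "D") + n_days)
    rain = np.where(np.arange(n_days) % rain_every == 0, rain_mm, 0.0)
    return m.WeatherSeries(dates, np.full(n_days, tmax), np.full(n_days, tmin),
                           np.full(n_days, srad), rain, latitude=latitude)


@pytest.fixture(scope="session")
def benign_weather():
    return make_constant_weather()


@pytest.fixture(scope="session")
def loamy_soil():
    return m.generate_soil("loamy")


def make_trial_from_cell_means(cell, reps=1, noise=None):
    """Wrap a p x q cell-mean array as a YieldTrial (replicating cells)."""
    cell = np.asarray(cell, dtype=float)
    p, q = cell.shape
    arr = np.repeat(cell[:, :, None], reps if reps > 1 else 2, axis=2)
    if noise is not None:
        arr = arr + noise
    return m.YieldTrial(arr,
                        tuple(f"G{i}" for i in range(p)),
                        tuple(f"E{j}" for j in range(q)),
                        tuple(f"R{k}" for k in range(arr.shape[2])))
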