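import numpy as np
import pandas as pd
import pytest

from ricegxe.synthetic import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Balanced 3-year trial, 40 lines x 2 replicates."""
    cfg = SimConfig(n_lines=40, n_markers=120, n_years=3, replicates=2,
                    drop_fraction=0.0, n_rows=5, n_cols=8, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def unbalanced_dataset():
    """Unbalanced 4-year trial with 50% line turnover (single replicate)."""
    cfg = SimConfig(n_lines=60, n_markers=200, n_years=4, replicates=1,
                    drop_fraction=0.5, n_rows=6, n_cols=10,
                    variance_targets={"Year": 0.432, "Genotype": 0.2, "GxY": 0.051,
                                      "Column": 0.0, "Row": 0.0, "Block": 0.0,
                                      "Residual": 0.317},
                    seed=23)
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)


def make_weather(days=120, start="2011-10-20", tmax=30.0, tmin=20.0, precip=None,
                 **overrides):
    """Minimal constant daily-weather frame for hand-computed EC checks."""
    dates = pd.date_range(start, periods=days, freq="D")
    df = pd.DataFrame({
        "date": dates,
        "tmax": tmax, "tmin": tmin, "tmean24": (tmax + tmin) / 2.0,
        "precipitation": 0.0 if precip is None else precip,
        "effective_precipitation": 0.0,
        "sunshine_hours": 6.0, "rh100_hours": 2.0, "min_rel_humidity": 50.0,
        "tank_evaporation": 4.0, "piche_evaporation": 3.0, "wind_run": 150.0,
    })
    for k, v in overrides.items():
        df[k] = v
    return df
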