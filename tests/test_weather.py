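"""Environmental-covariate derivation: phenology staging, Angstrom-Prescott
radiation, the 18 stage aggregates, and EC-matrix standardization."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_weather
from ricegxe.weather import (ECMatrix, PhenologyError, WeatherDataError,
                             angstrom_radiation, build_ec_matrix,
                             compute_stage_ec, derive_ec_table, stage_phenology,
                             validate_weather)

SOWING = pd.Timestamp("2011-10-20")


class TestPhenology:
    def test_window_boundaries(self):
        win = stage_phenology(SOWING, SOWING + pd.Timedelta(days=160), 100)
        assert (win.vegetative[0] - SOWING).days == 0
        assert (win.vegetative[1] - SOWING).days == 65
        assert (win.reproductive[0] - SOWING).days == 65
        assert (win.reproductive[1] - SOWING).days == 100
        assert (win.maturation[0] - SOWING).days == 100
        assert (win.maturation[1] - SOWING).days == 130

    def test_empty_vegetative_rejected(self):
        with pytest.raises(PhenologyError):
            stage_phenology(SOWING, SOWING + pd.Timedelta(days=160), 35)

    def test_truncated_maturation_rejected(self):
        with pytest.raises(PhenologyError):
            stage_phenology(SOWING, SOWING + pd.Timedelta(days=120), 100)

    def test_windows_tile_the_season(self):
        # days 0..130 each belong to exactly one stage (65 + 35 + 31 days)
        win = stage_phenology(SOWING, SOWING + pd.Timedelta(days=160), 100)
        counts = []
        for day in range(131):
            date = SOWING + pd.Timedelta(days=day)
            inside = [
                win.vegetative[0] <= date < win.vegetative[1],
                win.reproductive[0] <= date < win.reproductive[1],
                win.maturation[0] <= date <= win.maturation[1],
            ]
            counts.append(sum(inside))
        assert counts == [1] * 131
        lengths = [(win.vegetative[1] - win.vegetative[0]).days,
                   (win.reproductive[1] - win.reproductive[0]).days,
                   (win.maturation[1] - win.maturation[0]).days + 1]
        assert lengths == [65, 35, 31]


class TestAngstrom:
    def test_limits_and_hand_value(self):
        assert angstrom_radiation(0.0, 12.0, 800.0) == pytest.approx(0.25 * 800)
        assert angstrom_radiation(12.0, 12.0, 800.0) == pytest.approx(0.75 * 800)
        assert angstrom_radiation(6.0, 12.0, 800.0, a=0.25, b=0.50) == pytest.approx(400.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            angstrom_radiation(13.0, 12.0, 800.0)
        with pytest.raises(ValueError):
            angstrom_radiation(1.0, 0.0, 800.0)


class TestStageAggregates:
    def test_thermal_amplitude_mean(self):
        w = make_weather(days=2, tmax=pd.Series([30.0, 28.0]),
                         tmin=pd.Series([20.0, 22.0]))
        vec = compute_stage_ec(w, w["date"].iloc[0], w["date"].iloc[-1], closed_end=True)
        assert vec["ThermAmp"] == pytest.approx((10 + 6) / 2)

    def test_degree_days_not_truncated(self):
        w = make_weather(days=2, tmean24=pd.Series([25.0, 15.0]))
        vec = compute_stage_ec(w, w["date"].iloc[0], w["date"].iloc[-1], closed_end=True)
        assert vec["DegDay"] == pytest.approx((15 + 5) / 2)

    def test_cold_day_count_empty_when_warm(self):
        w = make_weather(days=5, tmin=16.0)
        vec = compute_stage_ec(w, w["date"].iloc[0], w["date"].iloc[-1], closed_end=True)
        assert vec["MinT15"] == 0

    def test_rain_day_count_and_sum(self):
        w = make_weather(days=4, precip=pd.Series([0.0, 3.2, 0.0, 1.1]))
        vec = compute_stage_ec(w, w["date"].iloc[0], w["date"].iloc[-1], closed_end=True)
        assert vec["PpitDay"] == 2
        assert vec["AccumPpit"] == pytest.approx(4.3)

    def test_missing_day_is_an_error(self):
        w = make_weather(days=5)
        with pytest.raises(WeatherDataError):
            compute_stage_ec(w, w["date"].iloc[0],
                             w["date"].iloc[-1] + pd.Timedelta(days=3))

    def test_missing_field_named(self):
        w = make_weather(days=3).drop(columns=["tank_evaporation"])
        with pytest.raises(WeatherDataError, match="TankEv"):
            compute_stage_ec(w, w["date"].iloc[0], w["date"].iloc[-1], closed_end=True)


class TestECMatrix:
    def _raw(self, n_years=3, seed=0):
        rng = np.random.default_rng(seed)
        weather, rows = {}, []
        for i in range(n_years):
            yr = 2010 + i
            w = make_weather(days=140, start=f"{yr}-10-20",
                             tmax=30.0 + rng.normal(0, 1),
                             tmin=20.0 + rng.normal(0, 1))
            w["precipitation"] = rng.exponential(2.0, size=140) * \
                (rng.random(140) < 0.4)
            w["sunshine_hours"] = np.clip(6 + rng.normal(0, 1, 140), 0, 10)
            w["tmean24"] = (w["tmax"] + w["tmin"]) / 2 + rng.normal(0, 0.3, 140)
            weather[yr] = w
            rows.append({"year": yr, "sowing": w["date"].iloc[0],
                         "harvest": w["date"].iloc[-1], "ft_days": 85})
        return weather, pd.DataFrame(rows)

    def test_54_columns_before_filtering(self):
        weather, seasons = self._raw()
        raw = derive_ec_table(weather, seasons)
        assert raw.shape == (3, 54)
        for stage in ("V", "R", "M"):
            assert sum(c.endswith(f"_{stage}") for c in raw.columns) == 18

    def test_constant_column_dropped(self):
        weather, seasons = self._raw()
        raw = derive_ec_table(weather, seasons)
        raw["Wind_V"] = 150.0
        ec = ECMatrix.from_raw(raw)
        assert "Wind_V" in ec.dropped
        assert "Wind_V" not in ec.values.columns

    def test_retained_columns_standardized(self):
        weather, seasons = self._raw()
        ec = ECMatrix.from_raw(derive_ec_table(weather, seasons))
        assert np.allclose(ec.values.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(ec.values.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_single_environment_rejected(self):
        weather, seasons = self._raw(n_years=1)
        with pytest.raises(ValueError):
            ECMatrix.from_raw(derive_ec_table(weather, seasons))

    def test_out_of_sample_uses_training_parameters_only(self):
        weather, seasons = self._raw(n_years=4)
        raw = derive_ec_table(weather, seasons)
        train = ECMatrix.from_raw(raw.iloc[:3])
        full = ECMatrix.from_raw(raw)
        # holding out a year must change the standardization parameters
        common = [c for c in train.center.index if c in full.center.index]
        assert not np.allclose(train.center[common], full.center[common])
        z = train.standardize_new(raw.iloc[3])
        manual = (raw.iloc[3][train.values.columns] - train.center) / train.scale
        assert np.allclose(z, manual)

    def test_build_from_stage_vectors(self):
        rng = np.random.default_rng(1)
        per_year = {
            yr: {s: pd.Series(rng.normal(size=18),
                              index=[f"V{i}" for i in range(18)])
                 for s in ("V", "R", "M")}
            for yr in (2010, 2011)
        }
        ec = build_ec_matrix(per_year)
        assert ec.n_raw_columns == 54

    def test_weather_invariant_violations_raise(self):
        w = make_weather(days=3)
        w.loc[1, "tmin"] = 40.0
        with pytest.raises(WeatherDataError):
            validate_weather(w)
        w2 = make_weather(days=3)
        w2.loc[2, "precipitation"] = -1.0
        with pytest.raises(WeatherDataError):
            validate_weather(w2)
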