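"""Derivation of stage-specific environmental covariates (EC) from daily weather.

A season's daily weather is summarized into 18 covariates per crop
developmental stage.  Stages are anchored on days to 50% flowering (FT):
the vegetative stage runs from sowing to FT - 35 days, the reproductive
stage covers the 35 days up to FT, and the maturation stage the 30 days
after FT (FT day inclusive).  With three stages this yields 54 columns per
environment (year); constant columns are dropped and the remainder centered
and scaled to unit variance, storing the centering parameters so that a new
year can be standardized without leaking its own statistics into the scale.

Solar radiation is reconstructed from sunshine hours with the
Angstrom-Prescott formula ``Rs = Ra (a + b n/N)`` using FAO-56 default
coefficients and standard solar geometry for day length and extraterrestrial
radiation at the trial latitude.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_LATITUDE",
    "ANGSTROM_A",
    "ANGSTROM_B",
    "STAGES",
    "EC_DEFINITIONS",
    "ECDefinition",
    "PhenologyWindow",
    "ECMatrix",
    "stage_phenology",
    "daylength",
    "extraterrestrial_radiation",
    "angstrom_radiation",
    "compute_stage_ec",
    "derive_ec_table",
    "build_ec_matrix",
    "validate_weather",
]

# Paso de la Laguna, Treinta y Tres, Uruguay (33 deg 15' S)
DEFAULT_LATITUDE = -33.25
# FAO-56 defaults for the Angstrom-Prescott coefficients
ANGSTROM_A = 0.25
ANGSTROM_B = 0.50
# MJ/m2 -> cal/cm2
_MJ_TO_CAL = 23.884

STAGES = ("V", "R", "M")

REQUIRED_FIELDS = [
    "date", "tmax", "tmin", "tmean24", "precipitation", "effective_precipitation",
    "sunshine_hours", "rh100_hours", "min_rel_humidity", "tank_evaporation",
    "piche_evaporation", "wind_run",
]

_NONNEG_FIELDS = ["precipitation", "effective_precipitation", "sunshine_hours",
                  "rh100_hours", "tank_evaporation", "piche_evaporation", "wind_run"]


class WeatherDataError(ValueError):
    """Missing or inconsistent daily weather data."""


def validate_weather(df: pd.DataFrame) -> None:
    """Check the daily-weather invariants; raise ``WeatherDataError`` if violated."""
    for f in REQUIRED_FIELDS:
        if f not in df.columns:
            raise WeatherDataError(f"missing weather field '{f}'")
    if np.any(df["tmax"].to_numpy() < df["tmin"].to_numpy()):
        raise WeatherDataError("tmax < tmin on some day")
    for f in _NONNEG_FIELDS:
        if np.any(df[f].to_numpy() < 0):
            raise WeatherDataError(f"negative values in '{f}'")
    dates = pd.to_datetime(df["date"])
    gaps = dates.diff().dropna()
    if len(gaps) and not (gaps == pd.Timedelta(days=1)).all():
        raise WeatherDataError("dates must be strictly increasing with no gaps")


# ---------------------------------------------------------------------------
# solar geometry
# ---------------------------------------------------------------------------

def _solar_terms(doy, lat_deg):
    phi = np.deg2rad(lat_deg)
    delta = 0.409 * np.sin(2.0 * np.pi / 365.0 * np.asarray(doy, dtype=float) - 1.39)
    x = np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0)
    ws = np.arccos(x)
    return phi, delta, ws


def daylength(doy, lat_deg: float = DEFAULT_LATITUDE):
    """Astronomical day length N (hours) for day-of-year and latitude."""
    _, _, ws = _solar_terms(doy, lat_deg)
    return 24.0 / np.pi * ws


def extraterrestrial_radiation(doy, lat_deg: float = DEFAULT_LATITUDE):
    """Extraterrestrial radiation Ra in cal/cm2/day (FAO-56 geometry)."""
    phi, delta, ws = _solar_terms(doy, lat_deg)
    d = np.asarray(doy, dtype=float)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi / 365.0 * d)
    gsc = 0.0820  # MJ m-2 min-1
    ra_mj = (24.0 * 60.0 / np.pi) * gsc * dr * (
        ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws)
    )
    return ra_mj * _MJ_TO_CAL


def angstrom_radiation(sunshine_hours, daylength_hours, extraterrestrial, a: float = ANGSTROM_A,
                       b: float = ANGSTROM_B):
    """Angstrom-Prescott solar radiation ``Ra * (a + b * n/N)``."""
    n = np.asarray(sunshine_hours, dtype=float)
    N = np.asarray(daylength_hours, dtype=float)
    if np.any(N <= 0):
        raise ValueError("day length must be positive")
    if np.any(n < 0) or np.any(n > N + 1e-9):
        raise ValueError("sunshine hours must lie in [0, daylength]")
    return np.asarray(extraterrestrial, dtype=float) * (a + b * n / N)


# ---------------------------------------------------------------------------
# phenology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenologyWindow:
    """Half-open vegetative/reproductive windows and closed-end maturation
    window tiling [sowing, FT + 30]."""

    vegetative: tuple  # [start, end)
    reproductive: tuple  # [start, end)
    maturation: tuple  # [start, end] inclusive end
    ft_date: object

    def stage_ranges(self):
        return {"V": (*self.vegetative, False),
                "R": (*self.reproductive, False),
                "M": (*self.maturation, True)}


class PhenologyError(ValueError):
    pass


def stage_phenology(sowing, harvest, ft_days_after_sowing: int) -> PhenologyWindow:
    """Anchor the three developmental stages on flowering time.

    Vegetative: [sowing, FT - 35); reproductive: [FT - 35, FT);
    maturation: [FT, FT + 30] inclusive.  FT must fall more than 35 days
    after sowing (otherwise the vegetative stage would be empty) and FT + 30
    must not exceed harvest (truncated maturation is an explicit error).
    """
    sowing = pd.Timestamp(sowing)
    harvest = pd.Timestamp(harvest)
    ft = int(ft_days_after_sowing)
    if ft <= 35:
        raise PhenologyError(
            f"flowering at {ft} days after sowing leaves an empty vegetative stage")
    ft_date = sowing + pd.Timedelta(days=ft)
    mat_end = ft_date + pd.Timedelta(days=30)
    if mat_end > harvest:
        raise PhenologyError(
            f"maturation would be truncated: FT + 30 ({mat_end.date()}) is after "
            f"harvest ({harvest.date()})")
    rep_start = ft_date - pd.Timedelta(days=35)
    return PhenologyWindow(
        vegetative=(sowing, rep_start),
        reproductive=(rep_start, ft_date),
        maturation=(ft_date, mat_end),
        ft_date=ft_date,
    )


# ---------------------------------------------------------------------------
# EC definitions (18 per stage)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ECDefinition:
    name: str
    aggregator: str  # 'mean' | 'sum' | 'count'
    daily_value: Callable
    unit: str
    description: str = ""


def _defs(degday_floor: bool = False, a: float = ANGSTROM_A, b: float = ANGSTROM_B):
    def degday(d, ctx):
        v = d["tmean24"] - 10.0
        return np.maximum(v, 0.0) if degday_floor else v

    return [
        ECDefinition("ThermAmp", "mean", lambda d, c: d["tmax"] - d["tmin"], "degC",
                     "average daily thermal amplitude"),
        ECDefinition("RelSun", "mean", lambda d, c: 100.0 * d["sunshine_hours"] / c["N"], "%",
                     "relative sunshine duration"),
        ECDefinition("SolRad", "mean",
                     lambda d, c: angstrom_radiation(d["sunshine_hours"], c["N"], c["Ra"], a, b),
                     "cal/cm2/day", "Angstrom-Prescott solar radiation"),
        ECDefinition("EfPpit", "mean", lambda d, c: d["effective_precipitation"], "mm",
                     "average effective precipitation"),
        ECDefinition("DegDay", "mean", degday, "degC",
                     "mean of daily average temperature minus 10"),
        ECDefinition("RelH", "sum", lambda d, c: d["rh100_hours"], "h",
                     "hours at 100% relative humidity"),
        ECDefinition("PpitDay", "count", lambda d, c: d["precipitation"] > 0, "days",
                     "days with rain"),
        ECDefinition("MeanTemp", "mean", lambda d, c: d["tmean24"], "degC",
                     "0-24h mean temperature"),
        ECDefinition("AvTemp", "mean", lambda d, c: (d["tmax"] + d["tmin"]) / 2.0, "degC",
                     "(max+min)/2 temperature"),
        ECDefinition("MaxTemp", "mean", lambda d, c: d["tmax"], "degC",
                     "average daily maximum temperature"),
        ECDefinition("MinTemp", "mean", lambda d, c: d["tmin"], "degC",
                     "average daily minimum temperature"),
        ECDefinition("TankEv", "mean", lambda d, c: d["tank_evaporation"], "mm",
                     "tank evaporation"),
        ECDefinition("Wind", "mean", lambda d, c: d["wind_run"], "km/day",
                     "wind run over 2 m"),
        ECDefinition("PicheEv", "mean", lambda d, c: d["piche_evaporation"], "mm",
                     "Piche evaporation"),
        ECDefinition("MinRelH", "mean", lambda d, c: d["min_rel_humidity"], "%",
                     "daily minimum relative humidity"),
        ECDefinition("AccumPpit", "sum", lambda d, c: d["precipitation"], "mm",
                     "accumulated precipitation"),
        ECDefinition("Sunhs", "sum", lambda d, c: d["sunshine_hours"], "h",
                     "total sunshine hours"),
        ECDefinition("MinT15", "count", lambda d, c: d["tmin"] < 15.0, "days",
                     "days with minimum temperature below 15"),
    ]


EC_DEFINITIONS = _defs()
EC_NAMES = [d.name for d in EC_DEFINITIONS]
EC_UNITS = {d.name: d.unit for d in EC_DEFINITIONS}


def compute_stage_ec(weather: pd.DataFrame, start, end, *, closed_end: bool = False,
                     definitions=None, latitude: float = DEFAULT_LATITUDE) -> pd.Series:
    """Aggregate daily weather over one stage window into the 18 EC values.

    ``weather`` must fully cover the window (a missing day raises
    ``WeatherDataError`` naming the date; a missing field names the field).
    """
    definitions = EC_DEFINITIONS if definitions is None else definitions
    start = pd.Timestamp(start)
    end = pd.Timestamp(end)
    dates = pd.to_datetime(weather["date"])
    sel = (dates >= start) & ((dates <= end) if closed_end else (dates < end))
    sub = weather.loc[sel]
    n_expected = (end - start).days + (1 if closed_end else 0)
    if len(sub) < n_expected:
        have = set(pd.to_datetime(sub["date"]).dt.normalize())
        want = pd.date_range(start, periods=n_expected, freq="D")
        missing = [d for d in want if d not in have]
        raise WeatherDataError(f"weather does not cover {missing[0].date()} in "
                               f"window [{start.date()}, {end.date()}]")
    doy = pd.to_datetime(sub["date"]).dt.dayofyear.to_numpy()
    ctx = {"N": daylength(doy, latitude), "Ra": extraterrestrial_radiation(doy, latitude)}
    values = {}
    for d in definitions:
        try:
            daily = np.asarray(d.daily_value(sub, ctx), dtype=float)
        except KeyError as exc:
            raise WeatherDataError(f"EC {d.name}: missing field {exc} in window "
                                   f"starting {start.date()}") from None
        if d.aggregator == "mean":
            values[d.name] = float(np.mean(daily))
        elif d.aggregator == "sum":
            values[d.name] = float(np.sum(daily))
        elif d.aggregator == "count":
            values[d.name] = float(np.sum(daily != 0))
        else:  # pragma: no cover
            raise ValueError(f"unknown aggregator {d.aggregator}")
    return pd.Series(values)


def derive_ec_table(weather_by_year: dict, seasons: pd.DataFrame, *,
                    latitude: float = DEFAULT_LATITUDE, definitions=None) -> pd.DataFrame:
    """Raw (unstandardized) EC table: one row per year, 54 suffixed columns.

    ``seasons`` needs columns year, sowing, harvest, ft_days (mean days to
    50% flowering for the year; per-year phenology is the default convention).
    """
    rows = {}
    for _, season in seasons.iterrows():
        yr = season["year"]
        weather = weather_by_year[yr]
        validate_weather(weather)
        win = stage_phenology(season["sowing"], season["harvest"], season["ft_days"])
        vals = {}
        for stage, (start, end, closed) in win.stage_ranges().items():
            vec = compute_stage_ec(weather, start, end, closed_end=closed,
                                   definitions=definitions, latitude=latitude)
            for name, v in vec.items():
                vals[f"{name}_{stage}"] = v
        rows[yr] = vals
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


# ---------------------------------------------------------------------------
# EC matrix
# ---------------------------------------------------------------------------

@dataclass
class ECMatrix:
    """Standardized environments-by-EC matrix with stored center/scale.

    ``values`` holds the retained (non-constant) columns, centered and scaled
    to unit sample variance over the training environments; ``raw`` keeps all
    columns before filtering.  ``standardize_new`` applies the stored training
    parameters to an out-of-sample year.
    """

    values: pd.DataFrame
    raw: pd.DataFrame
    center: pd.Series
    scale: pd.Series
    dropped: list = field(default_factory=list)

    @property
    def n_raw_columns(self) -> int:
        return self.raw.shape[1]

    @classmethod
    def from_raw(cls, raw: pd.DataFrame) -> "ECMatrix":
        if raw.shape[0] < 2:
            raise ValueError("cannot standardize EC with fewer than two environments")
        sd = raw.std(axis=0, ddof=1)
        tol = 1e-12 * (1.0 + raw.abs().mean(axis=0))
        dropped = list(raw.columns[sd <= tol])
        if dropped:
            log.info("dropping %d zero-variance EC column(s): %s", len(dropped), dropped)
        kept = raw.drop(columns=dropped)
        center = kept.mean(axis=0)
        scale = kept.std(axis=0, ddof=1)
        values = (kept - center) / scale
        return cls(values=values, raw=raw, center=center, scale=scale, dropped=dropped)

    def standardize_new(self, raw_row: pd.Series) -> pd.Series:
        """Standardize a new environment's raw EC with the stored training
        center/scale (no leakage)."""
        missing = [c for c in self.values.columns if c not in raw_row.index]
        if missing:
            raise ValueError(f"new environment is missing EC column(s): {missing}")
        row = raw_row[self.values.columns].astype(float)
        return (row - self.center) / self.scale

    def relationship(self) -> pd.DataFrame:
        """Environmental relationship Omega = W W'/q over the training years."""
        from .lmm import env_relationship
        om = env_relationship(self.values.to_numpy())
        return pd.DataFrame(om, index=self.values.index, columns=self.values.index)


def build_ec_matrix(per_year_stage_vectors: dict) -> ECMatrix:
    """Assemble the EC matrix from per-year stage vectors.

    ``per_year_stage_vectors`` maps year -> {stage -> Series of 18 values}.
    Constant columns are dropped (logged) and the rest centered/scaled.
    """
    rows = {}
    for yr, stages in per_year_stage_vectors.items():
        vals = {}
        for stage in STAGES:
            if stage not in stages:
                raise ValueError(f"year {yr}: missing stage {stage}")
            for name, v in stages[stage].items():
                vals[f"{name}_{stage}"] = float(v)
        rows[yr] = vals
    return ECMatrix.from_raw(pd.DataFrame.from_dict(rows, orient="index").sort_index())
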