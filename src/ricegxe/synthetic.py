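"""Synthetic multi-year rice trial generator with known ground truth.

Every downstream stage of the package (EC derivation, per-year BLUEs,
variance partition, reaction-norm prediction, PLS, GWAS, QTL-by-EC
regression) can be exercised against data whose generative effects are
recorded in a :class:`TruthSet`.

Design of the generator
-----------------------
* Genotypes are independent biallelic markers, dosage ~ Binomial(2, p) with
  the allele frequency drawn uniformly in [maf_min, maf_max]; columns whose
  empirical minor-allele frequency falls outside the band are redrawn.
* Daily weather is a sinusoidal seasonal mean plus AR(1) noise with
  year-specific offsets (temperature level, sunshine fraction, rain rate),
  so no EC is constant across years by construction; precipitation arrives
  as thinned exponential events.
* Trials are randomized complete block designs (one block per replicate,
  a row-by-column grid within each block).  In unbalanced mode a fraction of
  the previous year's lines is replaced by new lines each year, emulating a
  breeding program that drops ~50% of entries annually.
* Phenotypes follow the reaction-norm decomposition: grand mean + year
  effect (a linear combination of the year's standardized EC) + genotypic
  value (a linear combination of standardized marker dosages) + G-by-Y
  deviation (marker-by-EC products and/or iid cell effects) + block, row and
  column effects + residual.  Each component's realized effects are rescaled
  so their sample variance (ddof=1 over the component's own levels) equals
  the requested fraction of the total variance; the recorded
  ``realized_variances`` therefore match the targets exactly.

Randomness is fully reproducible: each component draws from its own stream
derived from the single configuration seed, so adding one component never
perturbs the draws of another.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .weather import ECMatrix, derive_ec_table

__all__ = [
    "SimConfig",
    "TruthSet",
    "GenotypeMatrix",
    "SimulatedDataset",
    "DEFAULT_VARIANCE_TARGETS",
    "simulate_genotypes",
    "simulate_weather",
    "simulate_trial_layout",
    "simulate_phenotypes",
    "simulate_dataset",
]

# Year / Genotype / GxY fractions follow the tropical japonica grain-yield
# variance profile of a multi-year Uruguayan breeding trial.
DEFAULT_VARIANCE_TARGETS = {
    "Year": 0.432,
    "Genotype": 0.132,
    "GxY": 0.051,
    "Column": 0.003,
    "Row": 0.005,
    "Block": 0.227,
    "Residual": 0.150,
}

_STREAMS = {"genotypes": 1, "weather": 2, "layout": 3, "phenotypes": 4}


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    n_lines: int = 320
    n_markers: int = 2000
    n_years: int = 5
    maf_min: float = 0.05
    maf_max: float = 0.5
    replicates: int = 2
    n_blocks: int | None = None  # defaults to the replicate count (RCBD)
    n_rows: int = 16
    n_cols: int = 20
    drop_fraction: float = 0.5
    variance_targets: dict = field(default_factory=lambda: dict(DEFAULT_VARIANCE_TARGETS))
    n_qtl: int = 20
    qtl_ec_slopes: dict = field(default_factory=dict)  # marker -> (EC name, slope)
    mu: float = 0.0
    total_variance: float = 1.0
    sowing_doy: int = 300
    season_length: int = 150
    ft_mean: float = 85.0
    ft_sd: float = 3.0
    first_year: int = 2009
    seed: int = 0

    def __post_init__(self):
        if self.n_lines < 2 or self.n_markers < 1 or self.n_years < 1:
            raise ConfigurationError("n_lines >= 2, n_markers >= 1, n_years >= 1 required")
        if not (0.0 < self.maf_min <= self.maf_max <= 0.5):
            raise ConfigurationError("need 0 < maf_min <= maf_max <= 0.5")
        if not (0.0 <= self.drop_fraction <= 1.0):
            raise ConfigurationError("drop_fraction must lie in [0, 1]")
        total = sum(self.variance_targets.values())
        if any(v < 0 for v in self.variance_targets.values()) or abs(total - 1.0) > 1e-8:
            raise ConfigurationError("variance_targets must be non-negative and sum to 1")
        if self.n_blocks is None:
            self.n_blocks = self.replicates

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],)))

    @property
    def years(self) -> list:
        return [self.first_year + i for i in range(self.n_years)]


@dataclass
class GenotypeMatrix:
    """Lines-by-markers allele dosage matrix (0/1/2) with a marker map."""

    dosage: pd.DataFrame
    map: pd.DataFrame  # marker, chrom, pos

    @property
    def lines(self):
        return list(self.dosage.index)

    @property
    def markers(self):
        return list(self.dosage.columns)

    def maf(self) -> pd.Series:
        f = self.dosage.mean(axis=0) / 2.0
        return np.minimum(f, 1.0 - f)

    def standardized(self, center=None, scale=None) -> pd.DataFrame:
        """Column-standardized dosages (monomorphic columns dropped)."""
        X = self.dosage
        keep = X.std(axis=0, ddof=1) > 0
        X = X.loc[:, keep]
        c = X.mean(axis=0) if center is None else center
        s = X.std(axis=0, ddof=1) if scale is None else scale
        return (X - c) / s

    def relationship(self) -> pd.DataFrame:
        from .lmm import genomic_relationship
        Xs = self.standardized()
        G = genomic_relationship(Xs.to_numpy())
        return pd.DataFrame(G, index=self.dosage.index, columns=self.dosage.index)


@dataclass
class TruthSet:
    marker_effects: pd.Series
    ec_effects: pd.Series
    interaction_effects: dict
    genotypic_values: pd.Series
    environment_effects: pd.Series
    gxy_effects: pd.Series
    design_effects: dict
    realized_variances: dict
    realized_fractions: dict

    def to_jsonable(self) -> dict:
        return {
            "marker_effects": self.marker_effects.to_dict(),
            "ec_effects": self.ec_effects.to_dict(),
            "interaction_effects": {f"{m}|{e}": v for (m, e), v in
                                    self.interaction_effects.items()},
            "genotypic_values": self.genotypic_values.to_dict(),
            "environment_effects": {str(k): v for k, v in
                                    self.environment_effects.to_dict().items()},
            "realized_variances": self.realized_variances,
            "realized_fractions": self.realized_fractions,
        }


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimConfig, n_lines: int | None = None, *,
                       maf_tol: float = 0.03) -> GenotypeMatrix:
    """Independent biallelic markers, dosage ~ Binomial(2, p).

    Markers whose empirical minor-allele frequency falls below ``maf_min`` or
    above ``maf_max + maf_tol`` are redrawn, so the simulated panel respects
    the MAF filter that real marker data would have passed.
    """
    n = config.n_lines if n_lines is None else int(n_lines)
    m = config.n_markers
    if n < 2 or m < 1:
        raise ConfigurationError("need at least 2 lines and 1 marker")
    rng = config.rng("genotypes")
    dosage = np.empty((n, m), dtype=np.int8)
    p = rng.uniform(config.maf_min, config.maf_max, size=m)
    todo = np.arange(m)
    for _ in range(200):
        draws = rng.binomial(2, p[todo], size=(n, len(todo)))
        f = draws.mean(axis=0) / 2.0
        emp_maf = np.minimum(f, 1.0 - f)
        ok = (emp_maf >= config.maf_min) & (emp_maf <= config.maf_max + maf_tol)
        dosage[:, todo[ok]] = draws[:, ok]
        todo = todo[~ok]
        if len(todo) == 0:
            break
        p[todo] = rng.uniform(config.maf_min, config.maf_max, size=len(todo))
    else:  # pragma: no cover
        raise RuntimeError("MAF rejection sampling failed to terminate")
    lines = [f"L{i + 1:04d}" for i in range(n)]
    markers = [f"M{j + 1:05d}" for j in range(m)]
    per_chrom = math.ceil(m / 12)
    mp = pd.DataFrame({
        "marker": markers,
        "chrom": [j // per_chrom + 1 for j in range(m)],
        "pos": [(j % per_chrom + 1) * 100_000 for j in range(m)],
    })
    return GenotypeMatrix(pd.DataFrame(dosage, index=lines, columns=markers), mp)


# ---------------------------------------------------------------------------
# weather
# ---------------------------------------------------------------------------

def simulate_weather(config: SimConfig, sowing_doy: int | None = None,
                     season_length: int | None = None, *,
                     base_temp: float = 21.0, seasonal_amplitude: float = 5.0,
                     diurnal_range: float = 10.0, noise_sd: float = 1.5,
                     rain_prob: float = 0.30, rain_mean: float = 8.0):
    """Daily weather for every simulated year.

    Returns ``(weather_by_year, seasons)`` where ``seasons`` has columns
    year, sowing, harvest, ft_days.  Year-specific offsets on temperature,
    sunshine fraction and rain rate guarantee between-year EC variance.
    """
    sowing_doy = config.sowing_doy if sowing_doy is None else int(sowing_doy)
    L = config.season_length if season_length is None else int(season_length)
    if L < 66:
        raise ConfigurationError("season_length must be >= 66 days so the "
                                 "phenology windows can be non-empty")
    rng = config.rng("weather")
    phi_ar = 0.6
    weather = {}
    seasons = []
    from .weather import daylength as _daylength
    for yr in config.years:
        t_off = rng.normal(0.0, 1.2)
        sun_off = rng.normal(0.0, 0.08)
        rain_scale = float(np.exp(rng.normal(0.0, 0.35)))
        wind_off = rng.normal(0.0, 15.0)

        d = np.arange(L)
        season = base_temp + seasonal_amplitude * np.sin(np.pi * d / L)
        e = np.zeros(L)
        if noise_sd > 0:
            eps = rng.normal(0.0, noise_sd * np.sqrt(1 - phi_ar**2), size=L)
            e[0] = rng.normal(0.0, noise_sd)
            for i in range(1, L):
                e[i] = phi_ar * e[i - 1] + eps[i]
        tmean = season + t_off + e
        half = diurnal_range / 2.0 + (rng.normal(0.0, 0.5, size=L) if noise_sd > 0 else 0.0)
        half = np.clip(half, 1.0, None)
        tmax = tmean + half
        tmin = tmean - half
        tmean24 = tmean + (rng.normal(0.0, 0.2, size=L) if noise_sd > 0 else 0.0)

        dates = pd.Timestamp(yr, 1, 1) + pd.to_timedelta(sowing_doy - 1 + d, unit="D")
        doy = dates.dayofyear.to_numpy()
        N = _daylength(doy)

        rain_ind = rng.random(L) < min(rain_prob * rain_scale, 0.9)
        precip = np.where(rain_ind, rng.exponential(rain_mean, size=L), 0.0)
        ef_precip = 0.75 * np.minimum(precip, 30.0)

        frac = np.clip(0.55 + sun_off + 0.03 * e - 0.45 * rain_ind, 0.0, 1.0)
        sunshine = frac * N
        rh100 = np.clip(2.0 + 6.0 * rain_ind + rng.normal(0.0, 1.0, size=L), 0.0, 24.0)
        minrh = np.clip(45.0 + 20.0 * rain_ind - 1.2 * (tmax - 25.0)
                        + rng.normal(0.0, 4.0, size=L), 5.0, 100.0)
        tank = np.clip(0.3 + 0.18 * tmean + 0.12 * sunshine
                       + rng.normal(0.0, 0.3, size=L), 0.1, None)
        piche = np.clip(0.7 * tank + rng.normal(0.0, 0.2, size=L), 0.05, None)
        wind = np.clip(140.0 + wind_off + rng.normal(0.0, 25.0, size=L), 10.0, None)

        weather[yr] = pd.DataFrame({
            "date": dates, "tmax": tmax, "tmin": tmin, "tmean24": tmean24,
            "precipitation": precip, "effective_precipitation": ef_precip,
            "sunshine_hours": sunshine, "rh100_hours": rh100,
            "min_rel_humidity": minrh, "tank_evaporation": tank,
            "piche_evaporation": piche, "wind_run": wind,
        })
        # FT drawn so that [FT - 35, FT + 30] always fits inside the season
        ft = int(np.clip(round(rng.normal(config.ft_mean, config.ft_sd)), 40, L - 31))
        seasons.append({"year": yr, "sowing": dates[0], "harvest": dates[-1],
                        "ft_days": ft})
    return weather, pd.DataFrame(seasons)


# ---------------------------------------------------------------------------
# trial layout
# ---------------------------------------------------------------------------

def simulate_trial_layout(config: SimConfig, year_index: int,
                          carryover_lines=None, new_line_names=None,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Plot skeleton (year, genotype, block, row, col) for one year.

    Balanced mode (``carryover_lines`` given, drop_fraction 0) keeps the line
    set; unbalanced mode replaces ``round(drop_fraction * n)`` lines with new
    identifiers, mirroring a program that drops ~50% of entries every year.
    """
    rng = config.rng("layout") if rng is None else rng
    n = config.n_lines
    if config.n_rows * config.n_cols < n:
        raise ConfigurationError(
            f"layout {config.n_rows}x{config.n_cols} cannot hold {n} lines")
    new_line_names = list(new_line_names or [])
    if carryover_lines is None:
        if len(new_line_names) < n:
            new_line_names = [f"L{i + 1:04d}" for i in range(n)]
        lines = list(new_line_names[:n])
    else:
        carry = list(carryover_lines)
        n_drop = round(config.drop_fraction * len(carry))
        if len(new_line_names) < n_drop:
            raise ConfigurationError(f"need {n_drop} new line names, got {len(new_line_names)}")
        kept_idx = rng.choice(len(carry), size=len(carry) - n_drop, replace=False)
        lines = [carry[i] for i in sorted(kept_idx)] + list(new_line_names[:n_drop])
    year = config.years[year_index]
    plots = []
    for b in range(config.replicates):
        order = rng.permutation(lines)
        for i, g in enumerate(order):
            plots.append({"year": year, "genotype": g, "block": f"B{b + 1}",
                          "row": i // config.n_cols + 1, "col": i % config.n_cols + 1})
    return pd.DataFrame(plots)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _scale_to(values: np.ndarray, target_var: float, what: str) -> np.ndarray:
    """Center and rescale so the ddof=1 sample variance equals target_var."""
    v = np.asarray(values, dtype=float)
    if target_var == 0.0:
        return np.zeros_like(v)
    c = v - v.mean()
    sd = c.std(ddof=1) if len(c) > 1 else 0.0
    if sd <= 0:
        raise ConfigurationError(
            f"cannot calibrate {what}: no variation among its {len(c)} level(s)")
    return c * (math.sqrt(target_var) / sd)


def simulate_phenotypes(genotypes: GenotypeMatrix, ec: ECMatrix,
                        layouts, config: SimConfig):
    """Phenotypes over the supplied plot skeletons, plus the generating truth.

    Each variance component is rescaled so its realized level variance equals
    ``variance_targets[name] * total_variance`` exactly (residual absorbs
    nothing; every component is calibrated independently).
    """
    if isinstance(layouts, dict):
        trial = pd.concat(list(layouts.values()), ignore_index=True)
    elif isinstance(layouts, pd.DataFrame):
        trial = layouts.copy()
    else:
        trial = pd.concat(list(layouts), ignore_index=True)
    targets = config.variance_targets
    tv = config.total_variance
    rng = config.rng("phenotypes")
    years = sorted(trial["year"].unique())
    missing_ec = [y for y in years if y not in ec.values.index]
    if missing_ec:
        raise ConfigurationError(f"EC matrix does not cover year(s) {missing_ec}")
    lines_obs = sorted(trial["genotype"].unique())
    absent = [g for g in lines_obs if g not in genotypes.dosage.index]
    if absent:
        raise ConfigurationError(f"{len(absent)} trial line(s) missing from genotypes")

    Xs = genotypes.standardized()
    W = ec.values.loc[years]

    # year effects: linear in the standardized EC
    gamma = rng.normal(size=W.shape[1])
    if len(years) > 1:
        w_year = _scale_to(W.to_numpy() @ gamma, targets.get("Year", 0.0) * tv, "Year")
    else:
        w_year = np.zeros(1)
    env_eff = pd.Series(w_year, index=years)

    # genotypic values: n_qtl markers with iid normal effects
    qtl_idx = rng.choice(Xs.shape[1], size=min(config.n_qtl, Xs.shape[1]), replace=False)
    b = np.zeros(Xs.shape[1])
    b[qtl_idx] = rng.normal(size=len(qtl_idx))
    g_all = Xs.to_numpy() @ b
    g_obs = pd.Series(g_all, index=Xs.index).loc[lines_obs]
    g_scaled = _scale_to(g_obs.to_numpy(), targets.get("Genotype", 0.0) * tv, "Genotype")
    geno_eff = pd.Series(g_scaled, index=lines_obs)
    # record effects on the same scale as the realized genotypic values
    raw_sd = g_obs.std(ddof=1)
    eff_scale = (math.sqrt(targets.get("Genotype", 0.0) * tv) / raw_sd) if raw_sd > 0 else 0.0
    marker_effects = pd.Series(b * eff_scale, index=Xs.columns)

    # G-by-Y deviations: marker-by-EC structured part plus iid cell noise
    cells = trial[["year", "genotype"]].drop_duplicates()
    cell_index = pd.MultiIndex.from_frame(cells)
    structured = np.zeros(len(cells))
    interaction_effects = {}
    for marker, (ec_name, slope) in config.qtl_ec_slopes.items():
        if marker not in Xs.columns:
            raise ConfigurationError(f"qtl_ec_slopes marker {marker} not in panel")
        if ec_name not in W.columns:
            raise ConfigurationError(f"qtl_ec_slopes EC {ec_name} not in EC matrix")
        xv = Xs[marker].reindex(cells["genotype"]).to_numpy()
        zv = W[ec_name].reindex(cells["year"]).to_numpy()
        structured += slope * xv * zv
        interaction_effects[(marker, ec_name)] = slope
    iid = rng.normal(size=len(cells))
    if interaction_effects:
        s_sd = structured.std(ddof=1)
        gxy_raw = structured + (0.2 * s_sd if s_sd > 0 else 1.0) * iid
    else:
        gxy_raw = iid
    if len(cells) > 1 and targets.get("GxY", 0.0) > 0:
        gxy = _scale_to(gxy_raw, targets["GxY"] * tv, "GxY")
    else:
        gxy = np.zeros(len(cells))
    gxy_eff = pd.Series(gxy, index=cell_index)

    # design effects: iid per level, calibrated; single-level terms fall to 0
    design_effects = {}
    realized = {"Year": float(env_eff.var(ddof=1)) if len(years) > 1 else 0.0,
                "Genotype": float(geno_eff.var(ddof=1)),
                "GxY": float(gxy_eff.var(ddof=1)) if len(cells) > 1 else 0.0}

    def _level_effect(name, key_series):
        levels = pd.unique(key_series)
        tgt = targets.get(name, 0.0) * tv
        if len(levels) < 2 or tgt == 0.0:
            if tgt > 0:
                warnings.warn(f"{name}: single level; its target variance is unrealized")
            eff = pd.Series(0.0, index=levels)
        else:
            eff = pd.Series(_scale_to(rng.normal(size=len(levels)), tgt, name), index=levels)
        design_effects[name] = eff
        realized[name] = float(eff.var(ddof=1)) if len(levels) > 1 else 0.0
        return key_series.map(eff).to_numpy()

    def _block_effect(blk_key, yr_key):
        """Block effects anchored to the two statistics a nested-model REML
        estimator sees: the within-year mean square (scaled to the target)
        and the year-average contribution (scaled to target / blocks-per-year
        and made orthogonal to the year effects, so the year stratum stays
        calibrated).  Blocks are the largest design component, so leakage
        into the year means would otherwise dominate Year recovery with few
        years."""
        tgt = targets.get("Block", 0.0) * tv
        pairs = pd.DataFrame({"level": blk_key, "parent": yr_key}).drop_duplicates("level")
        levels = pairs["level"].to_numpy()
        parent_of = pairs.set_index("level")["parent"]
        if len(levels) < 2 or tgt == 0.0:
            if tgt > 0:
                warnings.warn("Block: single level; its target variance is unrealized")
            eff = pd.Series(0.0, index=levels)
            design_effects["Block"] = eff
            realized["Block"] = 0.0
            return blk_key.map(eff).to_numpy()
        n_parents = parent_of.nunique()
        b_per_year = len(levels) / n_parents
        d = pd.Series(rng.normal(size=len(levels)), index=levels)
        d = d - d.groupby(parent_of).transform("mean")
        ss = float((d**2).sum())
        dof_within = len(levels) - n_parents
        if dof_within > 0 and ss > 0:
            d = d * math.sqrt(tgt * dof_within / ss)
        else:
            d[:] = 0.0
        u = pd.Series(rng.normal(size=n_parents), index=parent_of.unique())
        u = u - u.mean()
        wv = pd.Series({str(k): v for k, v in env_eff.items()}).reindex(u.index).fillna(0.0)
        if n_parents >= 3 and float(wv @ wv) > 0:
            u = u - (float(u @ wv) / float(wv @ wv)) * wv
        sd_u = u.std(ddof=1)
        if sd_u > 0 and b_per_year > 0:
            u = u * (math.sqrt(tgt / b_per_year) / sd_u)
        eff = d + parent_of.map(u)
        design_effects["Block"] = eff
        realized["Block"] = tgt if dof_within > 0 else float(eff.var(ddof=1))
        return blk_key.map(eff).to_numpy()

    yr_key = trial["year"].astype(str)
    blk_key = yr_key + ":" + trial["block"].astype(str)
    row_key = blk_key + ":" + trial["row"].astype(str)
    col_key = blk_key + ":" + trial["col"].astype(str)
    e_block = _block_effect(blk_key, yr_key)
    e_row = _level_effect("Row", row_key)
    e_col = _level_effect("Column", col_key)

    resid = _scale_to(rng.normal(size=len(trial)), targets.get("Residual", 0.0) * tv,
                      "Residual") if targets.get("Residual", 0.0) > 0 else np.zeros(len(trial))
    realized["Residual"] = float(np.var(resid, ddof=1)) if len(trial) > 1 else 0.0

    y = (config.mu
         + trial["year"].map(env_eff).to_numpy()
         + trial["genotype"].map(geno_eff).to_numpy()
         + gxy_eff.reindex(pd.MultiIndex.from_frame(trial[["year", "genotype"]])).to_numpy()
         + e_block + e_row + e_col + resid)
    out = trial.copy()
    out["trait"] = y

    total_realized = sum(realized.values())
    fractions = {k: (v / total_realized if total_realized > 0 else 0.0)
                 for k, v in realized.items()}
    ec_effects = pd.Series(gamma, index=W.columns)
    truth = TruthSet(marker_effects=marker_effects, ec_effects=ec_effects,
                     interaction_effects=interaction_effects,
                     genotypic_values=geno_eff, environment_effects=env_eff,
                     gxy_effects=gxy_eff, design_effects=design_effects,
                     realized_variances=realized, realized_fractions=fractions)
    return out, truth


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimConfig
    genotypes: GenotypeMatrix
    weather: dict
    seasons: pd.DataFrame
    ec_raw: pd.DataFrame
    ec: ECMatrix
    trial: pd.DataFrame
    truth: TruthSet


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the whole generator: genotypes, weather, EC, layouts, phenotypes."""
    if config.n_years < 2:
        raise ConfigurationError("a full dataset needs at least two years (EC standardization)")
    n_new_per_year = round(config.drop_fraction * config.n_lines)
    pool = config.n_lines + (config.n_years - 1) * n_new_per_year
    genotypes = simulate_genotypes(config, n_lines=pool)
    weather, seasons = simulate_weather(config)
    ec_raw = derive_ec_table(weather, seasons)
    ec = ECMatrix.from_raw(ec_raw)

    rng = config.rng("layout")
    names = genotypes.lines
    next_new = config.n_lines
    layouts = {}
    current = None
    for i, yr in enumerate(config.years):
        if current is None:
            layout = simulate_trial_layout(config, i, new_line_names=names[:config.n_lines],
                                           rng=rng)
        else:
            fresh = names[next_new:next_new + n_new_per_year]
            layout = simulate_trial_layout(config, i, carryover_lines=current,
                                           new_line_names=fresh, rng=rng)
            next_new += n_new_per_year
        layouts[yr] = layout
        current = sorted(layout["genotype"].unique())
    trial, truth = simulate_phenotypes(genotypes, ec, layouts, config)
    return SimulatedDataset(config=config, genotypes=genotypes, weather=weather,
                            seasons=seasons, ec_raw=ec_raw, ec=ec, trial=trial,
                            truth=truth)
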