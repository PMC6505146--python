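"""Reaction-norm genomic prediction of untested years.

Three nested mixed models are fitted to stacked per-year genotype means
(two-stage analysis):

* ``G``       y = mu + g + e,              g ~ N(0, G sg2)
* ``G+W``     y = mu + w + g + e,          w ~ N(0, Omega sw2)
* ``G+W+GW``  y = mu + w + g + gw + e,     gw ~ N(0, [Zg G Zg'] o Omega sgw2)

``G = X X'/p`` is the marker-derived genomic relationship, ``Omega = W W'/q``
the environmental relationship built from standardized environmental
covariates, and the interaction kernel is their observation-level Hadamard
product.  Prediction for a new year is the BLUP extension of the fitted
covariance model: the new environment's raw EC are standardized with the
*training* center/scale, its cross-covariance with the training years is
formed from the standardized covariates, and each random effect's
conditional mean is evaluated at the new environment.  Genotyped lines
without training phenotypes are predicted through their genomic relationship
with the training lines.

Accuracy for an untested year is the Pearson correlation between predictions
and that year's observed means ("leave one environment out").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import LMMFit, RandomTerm, interaction_kernel, reml_fit
from .weather import ECMatrix

__all__ = ["RNFit", "VARIANTS", "fit_reaction_norm", "predict_new_year",
           "loyo_evaluate", "pearson"]

VARIANTS = ("G", "G+W", "G+W+GW")


def pearson(pred, obs) -> float:
    """Product-moment correlation; errors on length < 3 or zero variance."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if pred.std() == 0 or obs.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(pred, obs)[0])


@dataclass
class RNFit:
    variant: str
    mu: float
    variance_components: dict
    fit: LMMFit = field(repr=False)
    G: pd.DataFrame = field(repr=False)
    omega: pd.DataFrame | None = field(repr=False)
    obs_lines: np.ndarray  # line label per training observation
    obs_years: np.ndarray  # year label per training observation
    training_years: list


def _check_variant(variant: str) -> str:
    if variant not in VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}; expected one of {VARIANTS}")
    return variant


def fit_reaction_norm(blues_long: pd.DataFrame, G: pd.DataFrame,
                      omega: pd.DataFrame | None, variant: str = "G+W+GW",
                      *, collapse_g: bool = True) -> RNFit:
    """Fit one reaction-norm variant to stacked per-year means.

    ``blues_long`` needs columns year, genotype, value; every genotype must
    appear in ``G`` and (for W variants) every year in ``omega``.  With
    ``collapse_g`` (default) the marker-only G model is fitted to per-line
    means over the training environments, the standard formulation for mean
    performance; pass ``collapse_g=False`` to keep stacked records (e.g. for
    likelihood comparisons against the W variants on identical data).
    """
    variant = _check_variant(variant)
    df = blues_long.dropna(subset=["value"]).reset_index(drop=True)
    if variant == "G" and collapse_g and df["year"].nunique() > 1:
        # unmodeled year main effects would otherwise contaminate the
        # genomic variance of the marker-only baseline
        df = (df.groupby("genotype", as_index=False)
                .agg(value=("value", "mean"), year=("year", "first")))
    y = df["value"].to_numpy(dtype=float)
    n = len(df)

    line_pos = pd.Index(G.index).get_indexer(df["genotype"])
    if np.any(line_pos < 0):
        missing = sorted(set(df["genotype"][line_pos < 0]))[:5]
        raise ValueError(f"genotype(s) not in G: {missing} ...")
    Zg = np.zeros((n, G.shape[0]))
    Zg[np.arange(n), line_pos] = 1.0
    terms = [RandomTerm("g", Z=Zg, K=G.to_numpy(), levels=list(G.index))]

    needs_omega = variant in ("G+W", "G+W+GW")
    if needs_omega:
        if omega is None:
            raise ValueError(f"variant {variant} requires an environmental kernel Omega")
        year_pos = pd.Index(omega.index).get_indexer(df["year"])
        if np.any(year_pos < 0):
            raise ValueError("some years are missing from Omega")
        Zw = np.zeros((n, omega.shape[0]))
        Zw[np.arange(n), year_pos] = 1.0
        terms.append(RandomTerm("w", Z=Zw, K=omega.to_numpy(), levels=list(omega.index)))
    if variant == "G+W+GW":
        Cg = Zg @ G.to_numpy() @ Zg.T
        Cw = Zw @ omega.to_numpy() @ Zw.T
        terms.append(RandomTerm("gw", Z=None, K=interaction_kernel(Cg, Cw)))

    fit = reml_fit(y, np.ones((n, 1)), terms)
    return RNFit(variant=variant, mu=float(fit.fixed_effects[0]),
                 variance_components=fit.variance_components, fit=fit, G=G,
                 omega=omega if needs_omega else None,
                 obs_lines=df["genotype"].to_numpy(),
                 obs_years=df["year"].to_numpy(),
                 training_years=sorted(pd.unique(df["year"])))


def predict_new_year(fit: RNFit, new_year_ec: pd.Series | None, target_lines,
                     train_ec: ECMatrix | None = None) -> pd.Series:
    """BLUP predictions for ``target_lines`` in an unobserved environment.

    The new year's raw EC vector is standardized with the training
    center/scale stored in ``train_ec``; the cross-covariances toward the
    training years are ``z_new . z_j / q``.  Lines that are genotyped but
    unphenotyped in training are predicted through the genomic relationship.
    """
    target_lines = list(target_lines)
    missing = [l for l in target_lines if l not in fit.G.index]
    if missing:
        raise ValueError(f"line(s) not in G: {missing[:5]}")
    unseen = [l for l in target_lines if l not in set(fit.obs_lines)]
    if unseen:
        warnings.warn(f"{len(unseen)} target line(s) have no training records; "
                      "their genetic effect comes from the relationship matrix only")
    Py = fit.fit.Py
    obs_line_pos = pd.Index(fit.G.index).get_indexer(fit.obs_lines)
    Gsub = fit.G.to_numpy()[pd.Index(fit.G.index).get_indexer(target_lines)][:, obs_line_pos]

    sg = fit.variance_components.get("g", 0.0)
    pred = fit.mu + sg * (Gsub @ Py)

    if fit.variant in ("G+W", "G+W+GW"):
        if train_ec is None or new_year_ec is None:
            raise ValueError("W variants need train_ec and the new year's raw EC")
        z_new = train_ec.standardize_new(new_year_ec).to_numpy()
        Ztrain = train_ec.values.to_numpy()
        omega_cross = pd.Series(Ztrain @ z_new / Ztrain.shape[1],
                                index=train_ec.values.index)
        ocross_obs = omega_cross.reindex(fit.obs_years).to_numpy()
        sw = fit.variance_components.get("w", 0.0)
        pred = pred + sw * float(ocross_obs @ Py)
        if fit.variant == "G+W+GW":
            sgw = fit.variance_components.get("gw", 0.0)
            pred = pred + sgw * ((Gsub * ocross_obs[None, :]) @ Py)
    return pd.Series(pred, index=target_lines)


def loyo_evaluate(blues_long: pd.DataFrame, G: pd.DataFrame, ec_raw: pd.DataFrame,
                  variants=VARIANTS, min_lines: int = 3) -> pd.DataFrame:
    """Leave-one-year-out evaluation of the requested model variants.

    For every held-out year the EC standardization, the environmental kernel
    and the model fit are rebuilt on the training years only.  Returns a
    DataFrame (variant, year, r, n).
    """
    years = sorted(pd.unique(blues_long["year"]))
    if len(years) < 2:
        raise ValueError("leave-one-year-out needs at least two years")
    results = []
    for held in years:
        train = blues_long[blues_long["year"] != held]
        test = blues_long[blues_long["year"] == held].dropna(subset=["value"])
        test = test[test["genotype"].isin(G.index)]
        if len(test) < min_lines:
            warnings.warn(f"held-out year {held}: fewer than {min_lines} scorable lines; skipped")
            continue
        train_years = sorted(pd.unique(train["year"]))
        needs_ec = any(v != "G" for v in variants)
        ec_train = omega = None
        if needs_ec:
            if len(train_years) < 2:
                warnings.warn(f"held-out year {held}: a single training year cannot "
                              "standardize EC; W variants skipped")
            else:
                ec_train = ECMatrix.from_raw(ec_raw.loc[train_years])
                omega = ec_train.relationship()
        for variant in variants:
            if variant != "G" and ec_train is None:
                continue
            fit = fit_reaction_norm(train, G, omega, variant=variant)
            pred = predict_new_year(
                fit, ec_raw.loc[held] if variant != "G" else None,
                test["genotype"].tolist(), ec_train)
            arr = pred.to_numpy()
            if np.std(arr) <= 1e-10 * (1.0 + np.abs(arr).max()):
                # all variance components at the boundary: no predictive
                # signal, scored as zero accuracy
                warnings.warn(f"held-out year {held}, {variant}: constant "
                              "predictions scored as r = 0")
                r = 0.0
            else:
                r = pearson(arr, test["value"].to_numpy())
            results.append({"variant": variant, "year": held, "r": r, "n": len(test)})
    return pd.DataFrame(results)
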