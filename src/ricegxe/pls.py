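"""Partial least squares (PLS1) regression by NIPALS.

PLS summarizes a wide, collinear predictor matrix (markers, or markers plus
environmental covariates) into a few latent variables T = X W chosen to
maximize covariance with the response, with the decomposition

    X = T P' + E,        y = T q' + f.

The regression coefficients on the original predictors use the corrected
weight transform R = W (P'W)^-1, b = R q', so that predictions from the
coefficients reproduce predictions from the scores exactly.  The number of
latent variables is chosen by minimizing the root mean squared error of
prediction (RMSEP) under seeded 10-fold cross-validation, with ties broken
toward fewer components.

Two model flavors mirror the genomic-prediction use case: PLS-G regresses
stacked per-year genotype means on marker dosages alone; PLS-GW adds the
year's environmental covariates (replicated across the lines of that year)
as extra predictor columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import standardize_columns

__all__ = ["PLSModel", "CVCurve", "fit_nipals", "select_components", "pls_predict",
           "rank_covariates", "build_pls_design", "pls_loyo_evaluate"]


@dataclass
class PLSModel:
    weights: np.ndarray        # W, predictors x c
    scores: np.ndarray         # T, observations x c
    x_loadings: np.ndarray     # P, predictors x c
    y_loadings: np.ndarray     # q, length c
    coefficients: pd.Series    # b on standardized predictors
    coef_path: np.ndarray = field(repr=False, default=None)  # predictors x c, cumulative
    n_components: int = 0
    predictor_center: np.ndarray = field(repr=False, default=None)
    predictor_scale: np.ndarray = field(repr=False, default=None)
    response_center: float = 0.0
    predictor_names: list = field(default_factory=list)
    residual_X: np.ndarray = field(repr=False, default=None)
    residual_y: np.ndarray = field(repr=False, default=None)


def fit_nipals(X, y, n_components: int, *, on_constant: str = "error") -> PLSModel:
    """Fit a univariate PLS model with ``n_components`` latent variables.

    ``X`` may be raw: columns are centered and scaled internally and the
    parameters stored on the model.  If the requested number of components
    exceeds the effective rank, the model is truncated with a warning.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else \
        [f"x{j}" for j in range(np.asarray(X).shape[1])]
    Xs, cx, sx = standardize_columns(np.asarray(X, dtype=float), on_constant=on_constant)
    y = np.asarray(y, dtype=float).ravel()
    n, p = Xs.shape
    if len(y) != n:
        raise ValueError("X and y are not conformable")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    cy = float(y.mean())
    yc = y - cy
    cmax = min(n_components, n - 1, p)

    W = np.zeros((p, cmax))
    T = np.zeros((n, cmax))
    P = np.zeros((p, cmax))
    q = np.zeros(cmax)
    R = np.zeros((p, cmax))          # corrected weights: T = Xs R
    Bpath = np.zeros((p, cmax))
    Xc = Xs.copy()
    yr = yc.copy()
    used = 0
    ynorm0 = max(np.linalg.norm(yc), 1e-300)
    for a in range(cmax):
        w = Xc.T @ yr
        nw = np.linalg.norm(w)
        if nw < 1e-10 * ynorm0 or np.linalg.norm(yr) < 1e-10 * ynorm0:
            break
        w /= nw
        t = Xc @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        pa = Xc.T @ t / tt
        qa = float(yr @ t) / tt
        Xc -= np.outer(t, pa)
        yr = yr - qa * t
        W[:, a], T[:, a], P[:, a], q[a] = w, t, pa, qa
        r = w.copy()
        for j in range(a):
            r -= float(P[:, j] @ w) * R[:, j]
        R[:, a] = r
        Bpath[:, a] = (Bpath[:, a - 1] if a else 0.0) + qa * r
        used = a + 1
    if used < n_components and used < cmax:
        warnings.warn(f"rank exhausted after {used} components "
                      f"(requested {n_components}); model truncated")
    elif cmax < n_components:
        warnings.warn(f"n_components truncated to {cmax} (rank limit)")
    coef = pd.Series(Bpath[:, used - 1] if used else np.zeros(p), index=names)
    return PLSModel(weights=W[:, :used], scores=T[:, :used], x_loadings=P[:, :used],
                    y_loadings=q[:used], coefficients=coef,
                    coef_path=Bpath[:, :used], n_components=used,
                    predictor_center=cx, predictor_scale=sx, response_center=cy,
                    predictor_names=names, residual_X=Xc, residual_y=yr)


def pls_predict(model: PLSModel, X_new, n_components: int | None = None) -> np.ndarray:
    """Predict responses for new observations (raw predictor scale)."""
    if isinstance(X_new, pd.DataFrame):
        missing = [c for c in model.predictor_names if c not in X_new.columns]
        if missing:
            raise ValueError(f"missing predictor column(s): {missing[:5]}")
        X_new = X_new[model.predictor_names]
    arr = np.atleast_2d(np.asarray(X_new, dtype=float))
    if arr.shape[1] != len(model.predictor_names):
        raise ValueError("predictor count mismatch")
    Xs = (arr - model.predictor_center) / model.predictor_scale
    if n_components is None:
        b = model.coefficients.to_numpy()
    else:
        if not (1 <= n_components <= model.n_components):
            raise ValueError("n_components out of fitted range")
        b = model.coef_path[:, n_components - 1]
    return model.response_center + Xs @ b


@dataclass
class CVCurve:
    rmsep: pd.Series   # indexed by component count
    chosen_c: int
    folds: int
    seed: int


def select_components(X, y, max_lv: int | None = None, folds: int = 10,
                      seed: int = 0) -> CVCurve:
    """Choose the latent-variable count by cross-validated RMSEP.

    Held-out squared errors are pooled over all folds before taking the root
    mean; the curve minimum picks ``chosen_c`` (ties to the smaller count).
    """
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = Xa.shape
    if n < folds:
        raise ValueError(f"need at least {folds} observations for {folds}-fold CV")
    if max_lv is None:
        max_lv = min(15, n - folds, p)
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_id = np.empty(n, dtype=int)
    fold_id[order] = np.arange(n) % folds
    sq_err = np.full((n, max_lv), np.nan)
    for f in range(folds):
        tr = fold_id != f
        te = ~tr
        model = fit_nipals(Xa[tr], y[tr], max_lv, on_constant="zero")
        Xs = (Xa[te] - model.predictor_center) / model.predictor_scale
        preds = model.response_center + Xs @ model.coef_path  # n_te x used
        used = model.n_components
        err = preds - y[te, None]
        sq_err[te, :used] = err**2
        if used < max_lv:  # rank-limited fold: carry the last fit forward
            sq_err[te, used:] = err[:, -1:]**2
    rmsep = pd.Series(np.sqrt(np.nanmean(sq_err, axis=0)),
                      index=pd.RangeIndex(1, max_lv + 1, name="components"))
    best = float(rmsep.min())
    chosen = int(rmsep.index[rmsep.to_numpy() <= best + 1e-12][0])
    return CVCurve(rmsep=rmsep, chosen_c=chosen, folds=folds, seed=seed)


def rank_covariates(model: PLSModel, subset=None) -> pd.DataFrame:
    """Coefficient ranking (|b| descending, signs preserved).

    ``subset`` filters predictor names: a list, a callable, or a suffix/regex
    string matched with ``pd.Series.str.contains``.
    """
    coef = model.coefficients
    if subset is not None:
        if callable(subset):
            keep = [n for n in coef.index if subset(n)]
        elif isinstance(subset, str):
            keep = list(coef.index[coef.index.str.contains(subset, regex=True)])
        else:
            keep = [n for n in subset if n in coef.index]
        coef = coef.loc[keep]
    if coef.empty:
        raise ValueError("covariate subset is empty")
    tab = pd.DataFrame({"name": coef.index, "coefficient": coef.to_numpy()})
    tab = tab.sort_values(["coefficient", "name"],
                          key=lambda s: -s.abs() if s.name == "coefficient" else s,
                          kind="mergesort").reset_index(drop=True)
    tab["rank"] = np.arange(1, len(tab) + 1)
    return tab


# ---------------------------------------------------------------------------
# genomic-prediction wrappers
# ---------------------------------------------------------------------------

def build_pls_design(blues_long: pd.DataFrame, geno_dosage: pd.DataFrame,
                     ec_raw: pd.DataFrame | None = None):
    """Stack the PLS design: marker dosages per observation, plus (PLS-GW)
    the year's raw EC replicated across the lines of that year."""
    df = blues_long.dropna(subset=["value"]).reset_index(drop=True)
    missing = [g for g in pd.unique(df["genotype"]) if g not in geno_dosage.index]
    if missing:
        raise ValueError(f"genotype(s) without markers: {missing[:5]}")
    X = geno_dosage.reindex(df["genotype"]).reset_index(drop=True)
    if ec_raw is not None:
        E = ec_raw.reindex(df["year"]).reset_index(drop=True)
        X = pd.concat([X, E], axis=1)
    return X, df["value"].to_numpy(), df


def pls_loyo_evaluate(blues_long: pd.DataFrame, geno_dosage: pd.DataFrame,
                      ec_raw: pd.DataFrame | None = None, *, folds: int = 10,
                      seed: int = 0, max_lv: int | None = None,
                      min_lines: int = 3) -> pd.DataFrame:
    """Leave-one-year-out accuracy of PLS-G (``ec_raw=None``) or PLS-GW."""
    years = sorted(pd.unique(blues_long["year"]))
    rows = []
    for held in years:
        train = blues_long[blues_long["year"] != held]
        test = blues_long[blues_long["year"] == held].dropna(subset=["value"])
        test = test[test["genotype"].isin(geno_dosage.index)]
        if len(test) < min_lines:
            warnings.warn(f"held-out year {held}: too few lines; skipped")
            continue
        Xtr, ytr, _ = build_pls_design(train, geno_dosage, ec_raw)
        curve = select_components(Xtr, ytr, max_lv=max_lv, folds=folds, seed=seed)
        model = fit_nipals(Xtr, ytr, curve.chosen_c, on_constant="zero")
        Xte, yte, _ = build_pls_design(test, geno_dosage, ec_raw)
        pred = pls_predict(model, Xte)
        from .reaction_norm import pearson
        rows.append({"year": held, "r": pearson(pred, yte), "n": len(test),
                     "chosen_c": curve.chosen_c})
    return pd.DataFrame(rows)
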