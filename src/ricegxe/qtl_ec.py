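"""Factorial regression of QTL effects on environmental covariates.

Second step of the two-step QTL-by-environment analysis: each marker that
passed the single-environment scan is regressed, across years, on one
environmental covariate at a time with the mixed model

    y_ij = mu + E_j + x_i (alpha_q + beta_q z_j + a_jq) + G_i + GE_ij

where y_ij is the mean of line i in year j, E_j a fixed year main effect,
x_i the marker dosage, alpha_q the QTL effect in the average environment,
beta_q the change of the QTL effect per unit of the (standardized)
covariate, a_jq ~ N(0, s_aq2) the residual year-specific QTL effect,
G_i ~ N(0, K sG2) the polygenic background, and GE_ij the remaining
genotype-by-environment effect whose covariance across years follows one of
three structures:

* CS  (compound symmetry): common covariance + homogeneous variances,
* HCS (heterogeneous CS): common covariance, year-specific variances,
* UN  (unstructured): a free symmetric year-by-year covariance.

CS and HCS are linear variance-component models and go through the shared
REML engine (the common covariance as a line main effect; the year-specific
variances as grouped residuals).  UN is fitted by direct optimization of the
restricted likelihood over a Cholesky parametrization.  Structures are
compared by BIC = -2 logL + k log(n) with k the number of estimated
covariance parameters; slopes are tested by a Wald z test and declared
across all (marker, EC) pairs with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .lmm import RandomTerm, bh_fdr, reml_fit
from .weather import ECMatrix

__all__ = ["QxEFit", "STRUCTURES", "fit_qtl_ec", "select_structure", "scan_qtl_by_ec"]

STRUCTURES = ("CS", "HCS", "UN")


class StructureInfeasibleError(ValueError):
    pass


@dataclass
class QxEFit:
    marker: str
    ec: str
    alpha_q: float
    beta_q: float
    wald_p: float
    residual_qtl_variance: float
    structure: str
    bic: float
    log_likelihood: float
    converged: bool
    n_parameters: int
    variance_components: dict = field(default_factory=dict)


def _prepare(blues_long, marker_dosage, ec_values, standardize_ec):
    df = blues_long.dropna(subset=["value"]).reset_index(drop=True)
    years = sorted(pd.unique(df["year"]))
    if len(years) < 2:
        raise ValueError("need at least two environments")
    z = ec_values.reindex(years).astype(float)
    if z.isna().any():
        raise ValueError("EC values missing for some year(s)")
    if standardize_ec:
        sd = z.std(ddof=1)
        if sd <= 1e-12:
            raise ValueError("EC is constant across environments; slope inestimable")
        z = (z - z.mean()) / sd
    elif z.std(ddof=1) <= 1e-12:
        raise ValueError("EC is constant across environments; slope inestimable")
    x = marker_dosage.reindex(df["genotype"]).astype(float)
    if x.isna().any():
        raise ValueError("marker dosage missing for some line(s)")
    x = x.to_numpy()
    if np.std(x) == 0:
        raise ValueError("marker is monomorphic among the scored lines")
    return df, years, z, x


def _design(df, years, z, x):
    n = len(df)
    year_codes = pd.Index(years).get_indexer(df["year"])
    E = np.zeros((n, len(years) - 1))
    for j in range(1, len(years)):
        E[year_codes == j, j - 1] = 1.0
    zobs = z.to_numpy()[year_codes]
    X = np.column_stack([np.ones(n), E, x, x * zobs])
    lines = pd.unique(df["genotype"])
    Zl = np.zeros((n, len(lines)))
    Zl[np.arange(n), pd.Index(lines).get_indexer(df["genotype"])] = 1.0
    Za = np.zeros((n, len(years)))
    Za[np.arange(n), year_codes] = x
    return X, Zl, Za, year_codes, lines


def fit_qtl_ec(blues_long: pd.DataFrame, marker_dosage: pd.Series,
               ec_values: pd.Series, structure: str = "CS",
               K: pd.DataFrame | None = None, *, standardize_ec: bool = True,
               marker: str = "marker", ec_name: str = "EC",
               max_un_environments: int = 5) -> QxEFit:
    """Fit the factorial-regression model for one (marker, EC) pair.

    The covariate is standardized over the training years by default, so
    ``beta_q`` is the change of the QTL effect per standard deviation of the
    covariate.  ``K`` is the kinship of the scored lines (identity if None).
    """
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}")
    df, years, z, x = _prepare(blues_long, marker_dosage, ec_values, standardize_ec)
    E = len(years)
    if structure in ("CS", "HCS") and E < 3:
        raise StructureInfeasibleError(f"{structure} needs >= 3 environments, got {E}")
    X, Zl, Za, year_codes, lines = _design(df, years, z, x)
    n, p = X.shape
    y = df["value"].to_numpy(dtype=float)
    Ksub = None
    if K is not None:
        Ksub = K.loc[lines, lines].to_numpy(dtype=float)

    terms = [RandomTerm("a_q", Z=Za, levels=list(years)),
             RandomTerm("polygenic", Z=Zl, K=Ksub, levels=list(lines))]
    if Ksub is None:
        # identity kinship would duplicate the CS line-main term
        terms = terms[:1]
        line_main_name = "polygenic"
        terms.append(RandomTerm("polygenic", Z=Zl, levels=list(lines)))
    else:
        terms.append(RandomTerm("line_main", Z=Zl, levels=list(lines)))
        line_main_name = "line_main"

    if structure == "CS":
        fit = reml_fit(y, X, terms)
        k = len(terms) + 1
        beta_idx = p - 1
        vc = fit.variance_components
        resid = vc["Residual"]
    elif structure == "HCS":
        fit = reml_fit(y, X, terms, residual_groups=np.asarray(years)[year_codes])
        k = len(terms) + E
        beta_idx = p - 1
        vc = fit.variance_components
        resid = float(np.mean([vc[f"Residual[{yr}]"] for yr in years]))
    else:
        if E > max_un_environments:
            raise StructureInfeasibleError(
                f"UN with {E} environments exceeds the {max_un_environments}-environment limit")
        n_sig = E * (E + 1) // 2
        if len(pd.unique(df["genotype"])) < 10 * (n_sig + 2):
            raise StructureInfeasibleError(
                "too few lines to support an unstructured covariance "
                "(need at least 10 lines per covariance parameter)")
        fit = _fit_unstructured(y, X, Za, Zl, Ksub, year_codes, E)
        k = 2 + n_sig
        beta_idx = p - 1
        vc = fit.variance_components
        resid = float(np.mean([vc[f"Sigma[{j},{j}]"] for j in range(E)]))

    beta_hat = float(fit.fixed_effects[beta_idx])
    se = float(np.sqrt(fit.fixed_cov[beta_idx, beta_idx]))
    wald_p = 2.0 * stats.norm.sf(abs(beta_hat) / se) if se > 0 else np.nan
    bic = -2.0 * fit.log_likelihood + k * np.log(n)
    return QxEFit(marker=marker, ec=ec_name,
                  alpha_q=float(fit.fixed_effects[p - 2]), beta_q=beta_hat,
                  wald_p=float(wald_p),
                  residual_qtl_variance=float(fit.variance_components.get("a_q", 0.0)),
                  structure=structure, bic=float(bic),
                  log_likelihood=float(fit.log_likelihood),
                  converged=fit.converged, n_parameters=k,
                  variance_components=dict(vc) | {"residual_mean": resid})


class _UNFit:
    def __init__(self, fixed_effects, fixed_cov, variance_components, ll, converged):
        self.fixed_effects = fixed_effects
        self.fixed_cov = fixed_cov
        self.variance_components = variance_components
        self.log_likelihood = ll
        self.converged = converged


def _un_loglik(theta, y, X, Ca, Cg, Zl, year_codes, E, n, p):
    sa2 = np.exp(theta[0])
    sg2 = np.exp(theta[1])
    Lc = np.zeros((E, E))
    idx = 2
    for j in range(E):
        for i in range(j, E):
            Lc[i, j] = theta[idx] if i != j else np.exp(theta[idx])
            idx += 1
    Sigma = Lc @ Lc.T
    same_line = Zl @ Zl.T
    Vge = same_line * Sigma[np.ix_(year_codes, year_codes)]
    V = sa2 * Ca + sg2 * Cg + Vge
    V[np.diag_indices(n)] += 1e-8 * np.trace(V) / n
    try:
        cf = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return np.inf, None
    Vi_y = cho_solve(cf, y)
    Vi_X = cho_solve(cf, X)
    XtViX = X.T @ Vi_X
    try:
        cfx = cho_factor(XtViX)
    except np.linalg.LinAlgError:
        return np.inf, None
    beta = cho_solve(cfx, X.T @ Vi_y)
    Py = Vi_y - Vi_X @ cho_solve(cfx, X.T @ Vi_y)
    logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
    logdetX = 2.0 * np.sum(np.log(np.diag(cfx[0])))
    ll = -0.5 * (logdetV + logdetX + y @ Py + (n - p) * np.log(2 * np.pi))
    cov = cho_solve(cfx, np.eye(p))
    return -ll, (beta, cov, Sigma, sa2, sg2)


def _fit_unstructured(y, X, Za, Zl, Ksub, year_codes, E) -> _UNFit:
    n, p = X.shape
    Ca = Za @ Za.T
    Cg = Zl @ (Ksub @ Zl.T) if Ksub is not None else Zl @ Zl.T
    # start from per-environment residual variances of the fixed-effects fit
    r0 = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    env_var = np.array([max(np.var(r0[year_codes == j], ddof=1), 1e-3 * np.var(y))
                        for j in range(E)])
    theta0 = np.concatenate([
        [np.log(0.05 * np.var(y)), np.log(0.1 * np.var(y))],
        [np.log(np.sqrt(0.7 * env_var[j])) if i == j else 0.0
         for j in range(E) for i in range(j, E)],
    ])
    res = optimize.minimize(lambda t: _un_loglik(t, y, X, Ca, Cg, Zl, year_codes,
                                                 E, n, p)[0],
                            theta0, method="Nelder-Mead",
                            options={"maxiter": 3000, "xatol": 1e-5, "fatol": 1e-7})
    nll, extras = _un_loglik(res.x, y, X, Ca, Cg, Zl, year_codes, E, n, p)
    if extras is None:
        raise RuntimeError("unstructured covariance fit failed")
    beta, cov, Sigma, sa2, sg2 = extras
    vc = {"a_q": sa2, "polygenic": sg2}
    for j in range(E):
        for i in range(j, E):
            vc[f"Sigma[{i},{j}]"] = float(Sigma[i, j])
            if i == j:
                vc[f"Sigma[{j},{j}]"] = float(Sigma[j, j])
    return _UNFit(beta, cov, vc, -nll, res.success)


def select_structure(fits) -> QxEFit:
    """Minimum-BIC structure among converged fits."""
    ok = [f for f in fits if f.converged]
    dropped = [f.structure for f in fits if not f.converged]
    if dropped:
        warnings.warn(f"non-converged structure(s) excluded: {dropped}")
    if not ok:
        raise ValueError("no converged structure fit to select from")
    return min(ok, key=lambda f: f.bic)


def structure_comparison(fits) -> pd.DataFrame:
    return pd.DataFrame([{"structure": f.structure, "log_likelihood": f.log_likelihood,
                          "n_parameters": f.n_parameters, "bic": f.bic,
                          "converged": f.converged} for f in fits])


def scan_qtl_by_ec(significant_markers: pd.DataFrame, ec_matrix,
                   blues_long: pd.DataFrame, geno_dosage: pd.DataFrame,
                   K: pd.DataFrame | None = None, *, structure: str = "auto",
                   alpha: float = 0.05, trait=None) -> pd.DataFrame:
    """Test every detected QTL against every available EC.

    ``significant_markers`` is the output of :func:`ricegxe.gwas.declare_qtl`
    (an empty table yields an empty result).  With ``structure='auto'`` the
    CS/HCS (and feasible UN) fits are compared by BIC on the first pair and
    the winning structure reused for all pairs, mirroring a global choice of
    covariance model; Wald p-values are collected across all (marker, EC)
    pairs and declared with BH-FDR at ``alpha``.
    """
    cols = ["trait", "marker", "chromosome", "position", "ec", "alpha", "beta",
            "wald_p", "structure", "fdr_significant"]
    if significant_markers.empty:
        return pd.DataFrame(columns=cols)
    ec_values = ec_matrix.values if isinstance(ec_matrix, ECMatrix) else ec_matrix
    markers = significant_markers.drop_duplicates("marker")
    chosen = structure if structure != "auto" else None
    rows = []
    for _, hit in markers.iterrows():
        m = hit["marker"]
        dosage = geno_dosage[m]
        for ec_name in ec_values.columns:
            zs = ec_values[ec_name]
            try:
                if chosen is None:
                    fits = []
                    for s in STRUCTURES:
                        try:
                            fits.append(fit_qtl_ec(blues_long, dosage, zs, s, K,
                                                   marker=m, ec_name=ec_name))
                        except (StructureInfeasibleError, ValueError):
                            continue
                    best = select_structure(fits)
                    chosen = best.structure
                    fit = best
                else:
                    fit = fit_qtl_ec(blues_long, dosage, zs, chosen, K,
                                     marker=m, ec_name=ec_name)
            except ValueError as exc:
                warnings.warn(f"{m} x {ec_name}: {exc}")
                continue
            rows.append({"trait": trait, "marker": m,
                         "chromosome": hit.get("chromosome"),
                         "position": hit.get("position"), "ec": ec_name,
                         "alpha": fit.alpha_q, "beta": fit.beta_q,
                         "wald_p": fit.wald_p, "structure": fit.structure})
    out = pd.DataFrame(rows, columns=cols[:-1])
    if out.empty:
        return pd.DataFrame(columns=cols)
    out["fdr_significant"] = bh_fdr(out["wald_p"].to_numpy(), alpha=alpha)
    return out
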