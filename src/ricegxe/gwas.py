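"""Single-environment mixed-model association scan (kinship model).

For one trait-year the per-year genotype means are tested marker by marker
under

    y = 1 mu + x beta_m + u + e,   u ~ N(0, K sG2),  e ~ N(0, se2 I)

with the kinship matrix K controlling polygenic background.  The default
fitting scheme estimates the variance components once under the null model
(no marker) and reuses them for every marker via an eigen-decomposition of
K, so each marker test is a generalized-least-squares regression in the
rotated space (the standard two-step approximation used by fast mixed-model
GWAS tools).  An exact mode that re-estimates the variance ratio per marker
is available for small problems.  The marker effect is reported per copy of
the alternative allele; the test statistic is the effect over its standard
error referred to a t distribution with n - 2 degrees of freedom, which
reduces exactly to the ordinary regression t test when K = I and the
polygenic variance is zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .lmm import bh_fdr

__all__ = ["scan_single_env", "declare_qtl", "null_reml"]


def _rotated_negll(log_delta, lam, Uy, UX):
    """Negative restricted log-likelihood profiled over the scale, as a
    function of delta = se2/sG2, in the eigenbasis of K."""
    delta = np.exp(log_delta)
    D = lam + delta
    w = 1.0 / D
    XtWX = (UX * w[:, None]).T @ UX
    XtWy = (UX * w[:, None]).T @ Uy
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        return np.inf
    r = Uy - UX @ beta
    n, p = UX.shape
    rss = float(r @ (w * r))
    sg2 = rss / (n - p)
    _, ld = np.linalg.slogdet(XtWX)
    ll = -0.5 * ((n - p) * np.log(2 * np.pi * sg2) + np.sum(np.log(D)) + ld + (n - p))
    return -ll


def null_reml(y, K, X=None):
    """REML variance components (sG2, se2) of the null kinship model.

    Uses the eigen-decomposition fast path: one eigh of K, then a 1-D search
    over the variance ratio.  Returns ``(sG2, se2, lam, U)``.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    X = np.ones((n, 1)) if X is None else np.asarray(X, dtype=float)
    K = np.asarray(K, dtype=float)
    lam, U = np.linalg.eigh((K + K.T) / 2.0)
    lam = np.clip(lam, 0.0, None)
    Uy = U.T @ y
    UX = U.T @ X
    grid = np.linspace(-10.0, 10.0, 41)
    vals = [_rotated_negll(g, lam, Uy, UX) for g in grid]
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(_rotated_negll, bounds=(lo, hi), method="bounded",
                                   args=(lam, Uy, UX))
    log_delta = float(res.x)
    if i == len(grid) - 1 and vals[i] <= res.fun:
        log_delta = grid[-1]  # boundary: essentially no polygenic variance
    delta = np.exp(log_delta)
    D = lam + delta
    w = 1.0 / D
    XtWX = (UX * w[:, None]).T @ UX
    beta = np.linalg.solve(XtWX, (UX * w[:, None]).T @ Uy)
    r = Uy - UX @ beta
    sg2 = float(r @ (w * r)) / (n - X.shape[1])
    se2 = sg2 * delta
    if delta >= np.exp(10.0) - 1:  # ratio at the boundary: report sG2 = 0
        return 0.0, float(np.var(y - X @ np.linalg.lstsq(X, y, rcond=None)[0], ddof=X.shape[1])), lam, U
    return sg2, se2, lam, U


def scan_single_env(blues: pd.Series, genotypes, K: pd.DataFrame,
                    marker_map: pd.DataFrame | None = None, *, year=None,
                    trait=None, method: str = "p3d", min_overlap: int = 30,
                    force_null_variances: tuple | None = None) -> pd.DataFrame:
    """Scan all markers for association with one year's genotype means.

    ``blues`` maps line -> adjusted mean; ``genotypes`` is the lines-by-
    markers dosage table (a :class:`~ricegxe.synthetic.GenotypeMatrix` is
    also accepted).  Missing dosages are mean-imputed per marker.
    ``force_null_variances=(sG2, se2)`` overrides the null REML estimates
    (useful to force the ordinary-regression limit with sG2 = 0).
    """
    if hasattr(genotypes, "dosage"):
        if marker_map is None:
            marker_map = genotypes.map
        genotypes = genotypes.dosage
    lines = [l for l in blues.index if l in genotypes.index and not pd.isna(blues[l])]
    if len(lines) < min_overlap:
        raise ValueError(f"only {len(lines)} lines shared between phenotypes and "
                         f"genotypes (minimum {min_overlap})")
    y = blues.loc[lines].to_numpy(dtype=float)
    M = genotypes.loc[lines].to_numpy(dtype=float)
    col_mean = np.nanmean(M, axis=0)
    nan_idx = np.where(np.isnan(M))
    M[nan_idx] = np.take(col_mean, nan_idx[1])
    Ksub = K.loc[lines, lines].to_numpy(dtype=float)
    n = len(lines)

    if force_null_variances is not None:
        sg2, se2 = map(float, force_null_variances)
        lam, U = np.linalg.eigh((Ksub + Ksub.T) / 2.0)
        lam = np.clip(lam, 0.0, None)
    else:
        sg2, se2, lam, U = null_reml(y, Ksub)

    D = sg2 * lam + se2
    if np.min(D) <= 0:
        D = np.maximum(D, 1e-12 * max(np.max(D), 1.0))
    w = 1.0 / D
    Uy = U.T @ y
    U1 = U.T @ np.ones(n)
    UM = U.T @ M

    mono = M.std(axis=0) == 0
    if method == "p3d":
        s11 = float(np.sum(w * U1 * U1))
        s1y = float(np.sum(w * U1 * Uy))
        syy = float(np.sum(w * Uy * Uy))
        s1x = (w * U1) @ UM
        sxx = w @ (UM * UM)
        sxy = (w * Uy) @ UM
        det = s11 * sxx - s1x**2
        det = np.where(mono | (det <= 1e-12 * s11 * np.maximum(sxx, 1e-300)), np.nan, det)
        beta = (s11 * sxy - s1x * s1y) / det
        beta0 = (sxx * s1y - s1x * sxy) / det
        rss = syy - beta0 * s1y - beta * sxy
        rss = np.maximum(rss, 0.0)
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 * s11 / det)
        tstat = beta / se
        pval = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    elif method == "exact":
        beta = np.full(M.shape[1], np.nan)
        pval = np.full(M.shape[1], np.nan)
        for j in range(M.shape[1]):
            if mono[j]:
                continue
            X = np.column_stack([np.ones(n), M[:, j]])
            sg2j, se2j, lamj, Uj = null_reml(y, Ksub, X=X)
            Dj = np.maximum(sg2j * lamj + se2j, 1e-12)
            wj = 1.0 / Dj
            UXj = Uj.T @ X
            Uyj = Uj.T @ y
            XtWX = (UXj * wj[:, None]).T @ UXj
            b = np.linalg.solve(XtWX, (UXj * wj[:, None]).T @ Uyj)
            r = Uyj - UXj @ b
            s2 = float(r @ (wj * r)) / (n - 2)
            cov = s2 * np.linalg.inv(XtWX)
            beta[j] = b[1]
            tj = b[1] / np.sqrt(cov[1, 1])
            pval[j] = 2.0 * stats.t.sf(abs(tj), df=n - 2)
    else:
        raise ValueError(f"unknown method {method!r}")

    out = pd.DataFrame({
        "marker": genotypes.columns,
        "effect": np.where(mono, 0.0, np.nan_to_num(beta, nan=0.0)),
        "pvalue": np.where(mono, np.nan, pval),
        "skipped": mono,
    })
    with np.errstate(divide="ignore"):
        out["score"] = np.where(out["pvalue"].notna(),
                                -np.log10(np.clip(out["pvalue"], 1e-300, None)), 0.0)
    if marker_map is not None:
        mm = marker_map.set_index("marker")
        out["chromosome"] = out["marker"].map(mm["chrom"])
        out["position"] = out["marker"].map(mm["pos"])
    else:
        out["chromosome"] = np.nan
        out["position"] = np.nan
    out["year"] = year
    out["trait"] = trait
    out.attrs["null_variances"] = (sg2, se2)
    out.attrs["n_lines"] = n
    return out[["marker", "chromosome", "position", "year", "trait",
                "effect", "score", "pvalue", "skipped"]]


def declare_qtl(scan: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Significant marker-trait associations under BH-FDR at ``alpha``."""
    tested = scan[~scan["skipped"] & scan["pvalue"].notna()]
    if tested.empty:
        return pd.DataFrame(columns=["marker", "chromosome", "position", "year",
                                     "effect", "score"])
    reject = bh_fdr(tested["pvalue"].to_numpy(), alpha=alpha)
    hits = tested.loc[reject, ["marker", "chromosome", "position", "year",
                               "effect", "score"]]
    return hits.sort_values("score", ascending=False).reset_index(drop=True)
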