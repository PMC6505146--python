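"""Linear mixed-model machinery shared by the whole package.

This module provides a REML engine for Gaussian mixed models of the form

    y = X beta + sum_k Z_k u_k + e,      u_k ~ N(0, K_k sigma_k^2)

where each random term carries an arbitrary known symmetric positive
semidefinite covariance kernel ``K_k`` (identity for ordinary factors, a
genomic relationship matrix ``G = X X'/p`` for genomic values, an
environmental relationship ``Omega`` built from standardized environmental
covariates, or a Hadamard product of the two for genotype-by-environment
interaction).  Variance components are estimated by average-information
REML with a monotone EM fallback; negative estimates are handled by pinning
components at the zero boundary and re-optimizing the remainder.

On top of the engine the module implements the standard multi-environment
trial analyses: per-year adjusted genotype means (BLUEs) from a model with
random block, row-within-block and column-within-block effects; line-mean
heritability; a multi-year variance partition into Year / Genotype / G-by-Y /
design / residual components; kernel constructors; and the
Benjamini-Hochberg step-up FDR procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RandomTerm",
    "LMMFit",
    "BLUESet",
    "VariancePartition",
    "reml_fit",
    "estimate_blues",
    "blues_by_year",
    "heritability",
    "heritability_by_year",
    "variance_partition",
    "genomic_relationship",
    "env_relationship",
    "interaction_kernel",
    "standardize_columns",
    "bh_fdr",
]

VARPART_COMPONENTS = ["Year", "Genotype", "GxY", "Column", "Row", "Block", "Residual"]


# ---------------------------------------------------------------------------
# kernels and helpers
# ---------------------------------------------------------------------------

def psd_factor(K: np.ndarray, name: str = "kernel", rtol: float = 1e-8) -> np.ndarray:
    """Return M with M M' = K, dropping numerically-zero eigenvalues.

    Raises ``ValueError`` if K is not symmetric PSD within tolerance.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(K, K.T, atol=1e-8 * (1.0 + np.abs(K).max())):
        raise ValueError(f"{name} must be symmetric")
    Ksym = (K + K.T) / 2.0
    w, U = np.linalg.eigh(Ksym)
    wmax = w[-1]
    if wmax <= 0:
        return np.zeros((K.shape[0], 0))
    if w[0] < -rtol * wmax:
        raise ValueError(f"{name} is not positive semidefinite (min eig {w[0]:.3e})")
    keep = w > rtol * wmax
    return U[:, keep] * np.sqrt(w[keep])


def genomic_relationship(X) -> np.ndarray:
    """Genomic relationship matrix ``G = X X' / p`` from standardized markers.

    ``X`` is a lines-by-markers matrix whose columns have been centered and
    scaled; columns with zero variance must be filtered upstream.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be a 2-D matrix with at least one column")
    sd = X.std(axis=0)
    nonzero = np.abs(X).max(axis=0) > 0
    if X.shape[0] > 1 and np.any((sd == 0) & nonzero):
        bad = int(np.sum((sd == 0) & nonzero))
        raise ValueError(f"{bad} zero-variance column(s) present; filter before building G")
    return X @ X.T / X.shape[1]


def env_relationship(W) -> np.ndarray:
    """Environmental relationship ``Omega = W W' / q`` from standardized EC."""
    return genomic_relationship(W)


def interaction_kernel(A, B) -> np.ndarray:
    """Hadamard (elementwise) product of two observation-level kernels.

    By the Schur product theorem the result is PSD when both factors are.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"kernel shapes do not match: {A.shape} vs {B.shape}")
    return A * B


def standardize_columns(X, center=None, scale=None, ddof: int = 1,
                        on_constant: str = "error"):
    """Center and scale columns to unit (sample) variance.

    Returns ``(Xs, center, scale)``.  With ``on_constant='zero'`` constant
    columns become all-zero instead of raising.
    """
    arr = np.asarray(X, dtype=float)
    if center is None:
        center = arr.mean(axis=0)
    if scale is None:
        scale = arr.std(axis=0, ddof=ddof) if arr.shape[0] > ddof else np.zeros(arr.shape[1])
    scale = np.asarray(scale, dtype=float).copy()
    const = scale <= 1e-12
    if np.any(const):
        if on_constant == "error":
            raise ValueError(f"{int(const.sum())} zero-variance column(s)")
        scale[const] = 1.0
    return (arr - center) / scale, np.asarray(center, dtype=float), scale


def bh_fdr(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR level ``alpha``."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject


def incidence(labels) -> tuple[np.ndarray, list]:
    """Dense 0/1 incidence matrix and the ordered level list for a factor."""
    codes, levels = pd.factorize(np.asarray(labels), sort=True)
    Z = np.zeros((len(codes), len(levels)))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z, list(levels)


# ---------------------------------------------------------------------------
# REML engine
# ---------------------------------------------------------------------------

@dataclass
class RandomTerm:
    """One random effect: incidence ``Z`` (None = observation level) and
    kernel ``K`` (None = identity)."""

    name: str
    Z: np.ndarray | None = None
    K: np.ndarray | None = None
    levels: list | None = None


@dataclass
class LMMFit:
    fixed_effects: np.ndarray
    fixed_names: list
    variance_components: dict
    blups: dict
    log_likelihood: float
    converged: bool
    n_iterations: int
    fixed_cov: np.ndarray
    Py: np.ndarray = field(repr=False, default=None)


class _Comp:
    """Internal component: either a low-rank factor M (cov = s*M M') or a
    diagonal mask (cov = s*diag(mask))."""

    def __init__(self, name, M=None, mask=None):
        self.name = name
        self.M = M
        self.mask = mask
        self.q = M.shape[1] if M is not None else int(mask.sum())

    def apply(self, v):
        if self.M is not None:
            return self.M @ (self.M.T @ v)
        return np.where(self.mask, v, 0.0)

    def add_to(self, V, s):
        if self.M is not None:
            V += s * (self.M @ self.M.T)
        else:
            idx = np.where(self.mask)[0]
            V[idx, idx] += s


def _build_comps(n, random_terms, residual_groups):
    comps = []
    terms_meta = []
    for t in random_terms:
        if t.Z is None and t.K is None:
            raise ValueError(f"term {t.name}: Z and K cannot both be None")
        if t.K is None:
            M = np.asarray(t.Z, dtype=float)
        else:
            F = psd_factor(t.K, name=f"kernel of term '{t.name}'")
            M = F if t.Z is None else np.asarray(t.Z, dtype=float) @ F
        if M.shape[0] != n:
            raise ValueError(f"term {t.name}: incidence has {M.shape[0]} rows, expected {n}")
        comps.append(_Comp(t.name, M=M))
        terms_meta.append(t)
    if residual_groups is None:
        comps.append(_Comp("Residual", mask=np.ones(n, dtype=bool)))
    else:
        groups = np.asarray(residual_groups)
        for g in pd.unique(groups):
            comps.append(_Comp(f"Residual[{g}]", mask=(groups == g)))
    return comps, terms_meta


def reml_fit(y, X, random_terms, *, residual_groups=None, tol: float = 1e-8,
             max_iter: int = 200, start=None) -> LMMFit:
    """Estimate variance components by average-information REML.

    The restricted log-likelihood is monotone non-decreasing across accepted
    iterations (AI steps are halved, and replaced by the monotone EM update,
    whenever they would decrease it).  Components driven to the zero boundary
    are pinned at zero and the remainder re-optimized.  Non-convergence within
    ``max_iter`` is flagged on the result, not raised.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y and X are not conformable")
    comps, terms_meta = _build_comps(n, random_terms, residual_groups)
    K = len(comps)
    names = [c.name for c in comps]

    vary = float(np.var(y))
    if vary < 1e-300:
        # degenerate: constant response -> every component at the boundary
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        blups = _compute_blups(terms_meta, np.zeros(n), {t.name: 0.0 for t in terms_meta})
        return LMMFit(beta, [f"b{j}" for j in range(p)], dict.fromkeys(names, 0.0),
                      blups, 0.0, True, 0, np.zeros((p, p)), np.zeros(n))

    floor = 1e-10 * vary

    def evaluate(sig):
        V = np.zeros((n, n))
        for s, c in zip(sig, comps):
            if s > 0:
                c.add_to(V, s)
        V[np.diag_indices(n)] += floor
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return None
        Li = solve_triangular(L, np.eye(n), lower=True)
        Vi = Li.T @ Li
        Vi_y = Vi @ y
        Vi_X = Vi @ X
        XtViX = X.T @ Vi_X
        try:
            cf = cho_factor(XtViX)
        except np.linalg.LinAlgError:
            return None
        beta = cho_solve(cf, X.T @ Vi_y)
        Py = Vi_y - Vi_X @ cho_solve(cf, X.T @ Vi_y)
        logdetV = 2.0 * np.sum(np.log(np.diag(L)))
        logdetXtViX = 2.0 * np.sum(np.log(np.diag(cf[0])))
        ll = -0.5 * (logdetV + logdetXtViX + y @ Py + (n - p) * np.log(2.0 * np.pi))
        return dict(L=L, Li=Li, Vi=Vi, Vi_X=Vi_X, cf=cf, beta=beta, Py=Py, ll=ll)

    if start is not None:
        sig = np.asarray(start, dtype=float).copy()
        if len(sig) != K:
            raise ValueError("start must supply one value per component")
        sig = np.maximum(sig, 0.0)
    else:
        r0 = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        v0 = max(float(np.var(r0, ddof=1)) if n > p else vary, 1e-12 * vary)
        sig = np.full(K, v0 / K)
    dead = np.array([c.q == 0 for c in comps])  # rank-zero kernels stay at 0
    sig[dead] = 0.0

    state = evaluate(sig)
    if state is None:
        sig = np.full(K, vary / K)
        sig[dead] = 0.0
        state = evaluate(sig)

    def run_opt(sig, state, frozen, iter_budget):
        """AI-REML iterations with EM fallback; ``frozen`` components are
        held at their current value.  Returns (sig, state, converged, iters,
        ai_se) where ai_se approximates the standard error of each active
        estimate from the inverse average-information matrix."""
        converged = False
        ll_prev = -np.inf
        ai_se = np.full(K, np.inf)
        it = 0
        for it in range(1, iter_budget + 1):
            Py = state["Py"]
            Vi = state["Vi"]
            Vi_X = state["Vi_X"]
            cf = state["cf"]
            free = ~frozen
            active = free & (sig > 0)
            trPC = np.zeros(K)
            yPCPy = np.zeros(K)
            t_vecs = np.zeros((K, n))
            for k, c in enumerate(comps):
                if frozen[k]:
                    continue
                if c.M is not None:
                    VM = Vi @ c.M
                    tr1 = float(np.sum(c.M * VM))
                    S = Vi_X.T @ c.M
                    tr2 = float(np.sum(S * cho_solve(cf, S)))
                else:
                    dVi = np.diag(Vi)
                    h = np.sum(Vi_X * (Vi_X @ cho_solve(cf, np.eye(Vi_X.shape[1]))),
                               axis=1)
                    tr1 = float(dVi[c.mask].sum())
                    tr2 = float(h[c.mask].sum())
                trPC[k] = tr1 - tr2
                t_vecs[k] = c.apply(Py)
                yPCPy[k] = float(Py @ t_vecs[k])
            score = -0.5 * (trPC - yPCPy)

            # wake components pinned at zero whose gradient is positive
            for k in range(K):
                if free[k] and sig[k] == 0.0 and score[k] > 0:
                    active[k] = True

            act = np.where(active)[0]
            Pt = np.zeros((len(act), n))
            for j, k in enumerate(act):
                v = Vi @ t_vecs[k]
                Pt[j] = v - Vi_X @ cho_solve(cf, X.T @ v)
            AI = 0.5 * (t_vecs[act] @ Pt.T)
            AI = (AI + AI.T) / 2.0
            AI[np.diag_indices_from(AI)] += 1e-8 * max(np.trace(AI), 1e-300)
            if len(act):
                try:
                    AIinv = np.linalg.inv(AI)
                    ai_se[act] = np.sqrt(np.maximum(np.diag(AIinv), 0.0))
                except np.linalg.LinAlgError:
                    pass

            # convergence: likelihood stalled AND first-order conditions hold
            # (scale-free gradient d ll / d log sigma ~ 0 for interior
            # components; boundary components must not want to increase)
            ll_now = state["ll"]
            scale_ll = 1.0 + abs(ll_now)
            kkt = all(
                (sig[k] <= 1e-8 * vary and score[k] <= 1e-3 * scale_ll)
                or abs(score[k]) * max(sig[k], 1e-6 * vary) <= 1e-5 * scale_ll
                for k in range(K) if free[k]
            )
            if (it > 1 and abs(ll_now - ll_prev) < tol * scale_ll and kkt) \
                    or len(act) == 0:
                converged = True
                break
            ll_prev = ll_now

            try:
                delta = np.linalg.solve(AI, score[act])
            except np.linalg.LinAlgError:
                delta = score[act] / np.maximum(np.diag(AI), 1e-300)

            ll_old = state["ll"]
            accepted = None
            step = delta.copy()
            for _ in range(12):
                cand = sig.copy()
                cand[act] = np.maximum(sig[act] + step, 0.0)
                st = evaluate(cand)
                if st is not None and st["ll"] >= ll_old - 1e-10:
                    accepted = (cand, st)
                    break
                step /= 2.0
            if accepted is None:
                # monotone EM update: s <- s + s^2/q * (y'PCPy - tr(PC))
                cand = sig.copy()
                for k in act:
                    q = comps[k].q
                    s = sig[k] if sig[k] > 0 else floor * 10
                    cand[k] = max(s + (s * s / max(q, 1)) * (yPCPy[k] - trPC[k]), 0.0)
                st = evaluate(cand)
                if st is None or st["ll"] < ll_old - 1e-6 * abs(ll_old):
                    break
                accepted = (cand, st)

            sig, state = accepted
            small = sig < 1e-8 * vary
            sig[small & free] = 0.0
        return sig, state, converged, it, ai_se

    sig, state, converged, it, ai_se = run_opt(sig, state, dead.copy(), max_iter)
    total_it = it

    # boundary probing: the restricted likelihood can have a second mode with
    # a weakly-determined component at zero; re-optimize with each such
    # component pinned and keep the better mode.
    probe = [k for k in range(K)
             if not dead[k] and sig[k] > 0 and sig[k] < 2.0 * ai_se[k]
             and comps[k].mask is None]
    for k in probe:
        cand = sig.copy()
        cand[k] = 0.0
        st = evaluate(cand)
        if st is None:
            continue
        frozen = dead.copy()
        frozen[k] = True
        c_sig, c_state, c_conv, c_it, _ = run_opt(cand, st, frozen, 50)
        total_it += c_it
        if c_conv and c_state["ll"] > state["ll"] + 1e-8:
            sig, state, converged = c_sig, c_state, c_conv
    it = total_it
    if not converged:
        warnings.warn("REML did not converge within max_iter; returning last estimates")

    sig = np.maximum(sig, 0.0)
    variance_components = dict(zip(names, (float(s) for s in sig)))
    blups = _compute_blups(terms_meta, state["Py"], variance_components)
    fixed_cov = cho_solve(state["cf"], np.eye(p))
    return LMMFit(state["beta"], [f"b{j}" for j in range(p)], variance_components,
                  blups, float(state["ll"]), converged, it, fixed_cov, state["Py"])


def _compute_blups(terms_meta, Py, variance_components):
    blups = {}
    for t in terms_meta:
        s = variance_components.get(t.name, 0.0)
        if t.Z is not None:
            v = np.asarray(t.Z).T @ Py
        else:
            v = Py.copy()
        if t.K is not None:
            v = np.asarray(t.K, dtype=float) @ v
        blups[t.name] = s * v
    return blups


# ---------------------------------------------------------------------------
# trial analyses
# ---------------------------------------------------------------------------

@dataclass
class BLUESet:
    """Per-year adjusted genotype means and the variance components of the
    model that produced them."""

    year: object
    blues: pd.Series
    model_variances: dict
    fit: LMMFit = field(repr=False, default=None)


def _design_random_terms(df, block="block", row="row", col="col"):
    terms = []
    if block in df.columns and df[block].nunique() > 1:
        Z, lev = incidence(df[block])
        terms.append(RandomTerm("Block", Z=Z, levels=lev))
    if row in df.columns and block in df.columns:
        key = df[block].astype(str) + ":" + df[row].astype(str)
        if key.nunique() > 1:
            Z, lev = incidence(key)
            terms.append(RandomTerm("Row", Z=Z, levels=lev))
    if col in df.columns and block in df.columns:
        key = df[block].astype(str) + ":" + df[col].astype(str)
        if key.nunique() > 1:
            Z, lev = incidence(key)
            terms.append(RandomTerm("Column", Z=Z, levels=lev))
    return terms


def estimate_blues(trial: pd.DataFrame, trait: str, *, genotype="genotype",
                   block="block", row="row", col="col", year=None) -> BLUESet:
    """Adjusted genotype means (BLUEs) for one year of trial data.

    Genotype is fitted as fixed; block, row-within-block and
    column-within-block as random.  Records with missing trait values are
    dropped; genotypes left without records are omitted with a warning.
    """
    df = trial
    if year is not None and "year" in df.columns:
        df = df[df["year"] == year]
    n_geno_all = df[genotype].nunique()
    df = df.dropna(subset=[trait])
    genos = pd.unique(df[genotype])
    if len(genos) < n_geno_all:
        warnings.warn(f"{n_geno_all - len(genos)} genotype(s) without records omitted")
    if df.empty:
        raise ValueError("no non-missing records")
    Xg, levels = incidence(df[genotype])
    terms = _design_random_terms(df, block=block, row=row, col=col)
    fit = reml_fit(df[trait].to_numpy(), Xg, terms)
    blues = pd.Series(fit.fixed_effects, index=levels, name=trait)
    return BLUESet(year=year, blues=blues, model_variances=fit.variance_components, fit=fit)


def blues_by_year(trial: pd.DataFrame, trait: str, **kw) -> pd.DataFrame:
    """Stacked per-year BLUEs: long DataFrame (year, genotype, value)."""
    out = []
    for yr in sorted(pd.unique(trial["year"])):
        bs = estimate_blues(trial, trait, year=yr, **kw)
        out.append(pd.DataFrame({"year": yr, "genotype": bs.blues.index,
                                 "value": bs.blues.to_numpy()}))
    return pd.concat(out, ignore_index=True)


def heritability(sigma_g2: float, sigma_e2: float, r: float) -> float:
    """Line-mean heritability ``H2 = sg2 / (sg2 + se2 / r)``."""
    if sigma_g2 < 0 or sigma_e2 < 0:
        raise ValueError("variances must be non-negative")
    if r < 1:
        raise ValueError("replicate count must be >= 1")
    if sigma_g2 == 0 and sigma_e2 == 0:
        raise ValueError("heritability undefined when both variances are zero")
    return sigma_g2 / (sigma_g2 + sigma_e2 / r)


def heritability_by_year(trial: pd.DataFrame, trait: str, *, genotype="genotype",
                         block="block", row="row", col="col") -> dict:
    """Per-year line-mean heritability.

    The genotypic variance comes from refitting the per-year model with
    genotype random; ``r`` is the median replicate count for the year.
    """
    out = {}
    for yr in sorted(pd.unique(trial["year"])):
        df = trial[trial["year"] == yr].dropna(subset=[trait])
        Zg, lev = incidence(df[genotype])
        terms = [RandomTerm("Genotype", Z=Zg, levels=lev)]
        terms += _design_random_terms(df, block=block, row=row, col=col)
        fit = reml_fit(df[trait].to_numpy(), np.ones((len(df), 1)), terms)
        r = float(df.groupby(genotype).size().median())
        out[yr] = heritability(fit.variance_components["Genotype"],
                               fit.variance_components["Residual"], r)
    return out


@dataclass
class VariancePartition:
    table: pd.DataFrame  # component, variance, percent
    fit: LMMFit = field(repr=False, default=None)

    def percent(self, component: str) -> float:
        row = self.table[self.table["component"] == component]
        return float(row["percent"].iloc[0])


def variance_partition(trial: pd.DataFrame, trait: str, *, genotype="genotype",
                       block="block", row="row", col="col") -> VariancePartition:
    """Partition multi-year trait variance into Year / Genotype / GxY /
    Column / Row / Block / Residual, all fitted as random in one model."""
    df = trial.dropna(subset=[trait])
    if df["year"].nunique() < 2:
        raise ValueError("variance partition requires at least two years")
    yr = df["year"].astype(str)
    terms = []
    specs = {
        "Year": yr,
        "Genotype": df[genotype].astype(str),
        "GxY": yr + ":" + df[genotype].astype(str),
        "Block": yr + ":" + df[block].astype(str),
        "Row": yr + ":" + df[block].astype(str) + ":" + df[row].astype(str),
        "Column": yr + ":" + df[block].astype(str) + ":" + df[col].astype(str),
    }
    for name, key in specs.items():
        if key.nunique() > 1:
            Z, lev = incidence(key)
            terms.append(RandomTerm(name, Z=Z, levels=lev))
        else:
            warnings.warn(f"component {name} has a single level; reported at 0")
    fit = reml_fit(df[trait].to_numpy(), np.ones((len(df), 1)), terms)
    var = {c: fit.variance_components.get(c, 0.0) for c in VARPART_COMPONENTS}
    total = sum(var.values())
    tab = pd.DataFrame({
        "component": VARPART_COMPONENTS,
        "variance": [var[c] for c in VARPART_COMPONENTS],
        "percent": [100.0 * var[c] / total if total > 0 else 0.0
                    for c in VARPART_COMPONENTS],
    })
    return VariancePartition(tab, fit)
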