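"""Seeded simulation experiments exercising the whole pipeline.

These routines back both the acceptance test suite and the standalone
acceptance script: each one generates data with the synthetic module (or a
small bespoke generator matching one model exactly), runs the corresponding
analysis, and returns the measured quantities.  Problem sizes are chosen so
the full battery runs on a single CPU in minutes while leaving the Monte
Carlo error comfortably inside the tolerances quoted in the tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import lmm, pls, qtl_ec, reaction_norm, synthetic
from .gwas import scan_single_env
from .synthetic import SimConfig, simulate_dataset, simulate_genotypes
from .weather import ECMatrix

__all__ = [
    "ec_column_counts", "varpart_recovery", "qtl_ec_slope_recovery",
    "reaction_norm_recovery", "gwas_null_calibration", "wald_type1_rate",
    "prediction_ordering",
]


def ec_column_counts(seed: int = 0, n_years: int = 3) -> dict:
    """Columns produced by the EC derivation on a multi-year weather fixture."""
    cfg = SimConfig(n_lines=4, n_markers=10, n_years=n_years, seed=seed)
    weather, seasons = synthetic.simulate_weather(cfg)
    from .weather import derive_ec_table
    raw = derive_ec_table(weather, seasons)
    ec = ECMatrix.from_raw(raw)
    return {"n_raw_columns": int(raw.shape[1]),
            "n_retained_columns": int(ec.values.shape[1]),
            "n_dropped": len(ec.dropped)}


def varpart_recovery(seed: int = 0, n_lines: int = 300, n_years: int = 3,
                     replicates: int = 2) -> dict:
    """Recover the generating Year/Genotype/GxY variance fractions.

    The generator is calibrated to the tropical-japonica grain-yield profile
    (Year 43.2%, Genotype 13.2%, GxY 5.1%); a balanced design is used so
    every component is estimable.
    """
    cfg = SimConfig(n_lines=n_lines, n_markers=400, n_years=n_years,
                    replicates=replicates, drop_fraction=0.0,
                    n_rows=15, n_cols=20, seed=seed)
    ds = simulate_dataset(cfg)
    vp = lmm.variance_partition(ds.trial, "trait")
    targets = {k: 100.0 * v for k, v in cfg.variance_targets.items()}
    recovered = {row["component"]: row["percent"] for _, row in vp.table.iterrows()}
    return {"targets_pct": targets, "recovered_pct": recovered,
            "abs_error": {k: abs(recovered[k] - targets[k]) for k in targets}}


def _safe_pearson(pred, obs) -> float:
    """Pearson r, scoring degenerate (constant) predictions as 0 accuracy."""
    arr = np.asarray(pred, dtype=float)
    if np.std(arr) <= 1e-10 * (1.0 + np.abs(arr).max()):
        return 0.0
    return reaction_norm.pearson(pred, obs)


def _factorial_sim(rng, n_lines, n_envs, alpha, beta, *, sigma_aq=0.0,
                   sigma_g=0.3, sigma_line=0.2, sigma_e=0.5, Xmk=None):
    """One draw from the factorial-regression generative model."""
    lines = [f"L{i:03d}" for i in range(n_lines)]
    years = list(range(2001, 2001 + n_envs))
    x = rng.binomial(2, 0.3, size=n_lines).astype(float)
    while np.std(x) == 0:
        x = rng.binomial(2, 0.3, size=n_lines).astype(float)
    z = rng.normal(size=n_envs)
    z = (z - z.mean()) / z.std(ddof=1)
    if Xmk is None:
        Xmk = rng.binomial(2, rng.uniform(0.1, 0.5, size=200), size=(n_lines, 200)).astype(float)
    Xs, *_ = lmm.standardize_columns(Xmk, on_constant="zero")
    K = lmm.genomic_relationship(Xs + rng.normal(0, 1e-6, Xs.shape))
    Lk = np.linalg.cholesky(K + 1e-6 * np.eye(n_lines))
    g = sigma_g * (Lk @ rng.normal(size=n_lines))
    line_main = sigma_line * rng.normal(size=n_lines)
    a_j = sigma_aq * rng.normal(size=n_envs)
    env_main = rng.normal(0, 0.5, size=n_envs)
    rows = []
    for j, yr in enumerate(years):
        e = sigma_e * rng.normal(size=n_lines)
        y = (env_main[j] + x * (alpha + beta * z[j] + a_j[j]) + g + line_main + e)
        rows.append(pd.DataFrame({"year": yr, "genotype": lines, "value": y}))
    blues = pd.concat(rows, ignore_index=True)
    return blues, pd.Series(x, index=lines), pd.Series(z, index=years), \
        pd.DataFrame(K, index=lines, columns=lines)


def qtl_ec_slope_recovery(seed: int = 0, n_reps: int = 20, alpha: float = 0.4,
                          beta: float = 0.3, n_lines: int = 300,
                          n_envs: int = 4) -> dict:
    """Mean estimated QTL-by-EC slope over seeded replicates (truth 0.3)."""
    rng = np.random.default_rng(seed)
    betas, alphas = [], []
    for _ in range(n_reps):
        blues, x, z, K = _factorial_sim(rng, n_lines, n_envs, alpha, beta,
                                        sigma_aq=0.05)
        fit = qtl_ec.fit_qtl_ec(blues, x, z, "CS", K, standardize_ec=False)
        betas.append(fit.beta_q)
        alphas.append(fit.alpha_q)
    return {"beta_truth": beta, "beta_mean": float(np.mean(betas)),
            "beta_sd": float(np.std(betas, ddof=1)),
            "alpha_truth": alpha, "alpha_mean": float(np.mean(alphas))}


def wald_type1_rate(seed: int = 0, n_reps: int = 1000, n_lines: int = 50,
                    n_envs: int = 5, level: float = 0.05) -> dict:
    """Empirical rejection rate of the slope Wald test under beta = 0."""
    rng = np.random.default_rng(seed)
    Xmk = rng.binomial(2, rng.uniform(0.1, 0.5, size=150),
                       size=(n_lines, 150)).astype(float)
    rejections = 0
    tested = 0
    for _ in range(n_reps):
        blues, x, z, K = _factorial_sim(rng, n_lines, n_envs, alpha=0.3, beta=0.0,
                                        Xmk=Xmk)
        fit = qtl_ec.fit_qtl_ec(blues, x, z, "CS", K, standardize_ec=False)
        tested += 1
        if fit.wald_p < level:
            rejections += 1
    return {"rate": rejections / tested, "n_reps": tested, "level": level}


def _eq6_sim(rng, n_lines, n_years, sg2, sw2, sgw2, se2, n_markers=400, n_ec=30):
    """Data from the full reaction-norm model with kernel-structured effects.

    Effect vectors are rescaled so their realized variance (quadratic form in
    the kernel pseudo-inverse over its rank) equals the nominal component,
    which keeps single-realization REML estimates anchored at the truth.
    """
    lines = [f"L{i:03d}" for i in range(n_lines)]
    years = list(range(2001, 2001 + n_years))
    Xmk = rng.binomial(2, rng.uniform(0.1, 0.5, size=n_markers),
                       size=(n_lines, n_markers)).astype(float)
    Xs, *_ = lmm.standardize_columns(Xmk, on_constant="zero")
    G = lmm.genomic_relationship(Xs)
    W = rng.normal(size=(n_years, n_ec))
    W, *_ = lmm.standardize_columns(W)
    Om = lmm.env_relationship(W)

    def draw(Kmat, s2):
        if s2 == 0:
            return np.zeros(Kmat.shape[0])
        w, U = np.linalg.eigh((Kmat + Kmat.T) / 2)
        keep = w > 1e-10 * w[-1]
        zr = rng.normal(size=keep.sum())
        zr *= np.sqrt(s2 * keep.sum() / (zr @ zr))
        return (U[:, keep] * np.sqrt(w[keep])) @ zr

    g = draw(G, sg2)
    wv = draw(Om, sw2)
    n = n_lines * n_years
    Zg = np.kron(np.ones((n_years, 1)), np.eye(n_lines))
    Zw = np.kron(np.eye(n_years), np.ones((n_lines, 1)))
    Kgw = (Zg @ G @ Zg.T) * (Zw @ Om @ Zw.T)
    gw = draw(Kgw, sgw2)
    e = rng.normal(size=n)
    e *= np.sqrt(se2 * n / (e @ e))
    y = Zg @ g + Zw @ wv + gw + e
    blues = pd.DataFrame({"year": np.repeat(years, n_lines),
                          "genotype": np.tile(lines, n_years), "value": y})
    return blues, pd.DataFrame(G, index=lines, columns=lines), \
        pd.DataFrame(Om, index=years, columns=years)


def reaction_norm_recovery(seed: int = 0, n_lines: int = 300, n_years: int = 4,
                           sg2: float = 0.3, sw2: float = 0.6, sgw2: float = 0.3,
                           se2: float = 0.25, n_reps: int = 3) -> dict:
    """Relative error of the reaction-norm variance components.

    Generating values mimic a quality trait with a dominant year component
    and an interaction as large as the genotype main effect (the head-rice
    pattern in multi-year subtropical trials).  Estimates are averaged over
    ``n_reps`` independent draws to damp Monte-Carlo noise in the
    interaction/residual split."""
    rng = np.random.default_rng(seed)
    truth = {"g": sg2, "w": sw2, "gw": sgw2, "Residual": se2}
    sums = dict.fromkeys(truth, 0.0)
    for _ in range(n_reps):
        blues, G, Om = _eq6_sim(rng, n_lines, n_years, sg2, sw2, sgw2, se2)
        fit = reaction_norm.fit_reaction_norm(blues, G, Om, "G+W+GW")
        for k in truth:
            sums[k] += fit.variance_components[k]
    est = {k: v / n_reps for k, v in sums.items()}
    rel = {k: abs(est[k] - truth[k]) / truth[k] for k in truth}
    return {"truth": truth, "estimates": est, "relative_error": rel,
            "max_relative_error": max(rel.values())}


def gwas_null_calibration(seed: int = 0, n_lines: int = 200,
                          n_markers: int = 2000) -> dict:
    """Fraction of null-marker p-values below 0.05 (expected 0.05)."""
    cfg = SimConfig(n_lines=n_lines, n_markers=n_markers, n_years=2, seed=seed)
    geno = simulate_genotypes(cfg)
    rng = np.random.default_rng(seed + 1)
    y = pd.Series(rng.normal(size=n_lines), index=geno.lines)
    K = geno.relationship()
    scan = scan_single_env(y, geno, K)
    p = scan.loc[~scan["skipped"], "pvalue"].to_numpy()
    return {"fraction_below_0p05": float(np.mean(p < 0.05)), "n_markers": len(p)}


def prediction_ordering(seed: int = 0, n_reps: int = 20, n_lines: int = 120,
                        n_years: int = 4, n_markers: int = 500) -> dict:
    """Mean leave-one-year-out accuracy of G, G+W, PLS-G and PLS-GW.

    The generating conditions mirror the unbalanced multi-year breeding
    trial: a dominant year component (43%), half of the lines replaced every
    year, and year effects that are linear in the environmental covariates.
    One year per replicate is held out (rotating), giving n_reps held-out
    evaluations per model.
    """
    targets = {"Year": 0.432, "Genotype": 0.20, "GxY": 0.051, "Column": 0.0,
               "Row": 0.0, "Block": 0.0, "Residual": 0.317}
    acc = {m: [] for m in ("G", "G+W", "PLS-G", "PLS-GW")}
    for rep in range(n_reps):
        cfg = SimConfig(n_lines=n_lines, n_markers=n_markers, n_years=n_years,
                        replicates=1, drop_fraction=0.5, n_rows=12, n_cols=10,
                        variance_targets=targets, n_qtl=40, seed=seed + rep)
        ds = simulate_dataset(cfg)
        blues = ds.trial.rename(columns={"trait": "value"})[["year", "genotype", "value"]]
        G = ds.genotypes.relationship()
        held = sorted(blues["year"].unique())[rep % n_years]
        train = blues[blues["year"] != held]
        test = blues[blues["year"] == held]

        ec_train = ECMatrix.from_raw(ds.ec_raw.loc[sorted(train["year"].unique())])
        omega = ec_train.relationship()
        for variant in ("G", "G+W"):
            fit = reaction_norm.fit_reaction_norm(
                train, G, omega if variant != "G" else None, variant=variant)
            pred = reaction_norm.predict_new_year(
                fit, ds.ec_raw.loc[held] if variant != "G" else None,
                test["genotype"].tolist(), ec_train)
            acc[variant].append(_safe_pearson(pred.to_numpy(),
                                              test["value"].to_numpy()))
        for label, ec in (("PLS-G", None), ("PLS-GW", ds.ec_raw)):
            Xtr, ytr, _ = pls.build_pls_design(train, ds.genotypes.dosage, ec)
            curve = pls.select_components(Xtr, ytr, max_lv=10, seed=seed + rep)
            model = pls.fit_nipals(Xtr, ytr, curve.chosen_c, on_constant="zero")
            Xte, yte, _ = pls.build_pls_design(test, ds.genotypes.dosage, ec)
            acc[label].append(_safe_pearson(pls.pls_predict(model, Xte), yte))
    return {f"mean_r_{k}": float(np.mean(v)) for k, v in acc.items()} | {
        "n_reps": n_reps,
        "delta_GW_minus_G": float(np.mean(acc["G+W"]) - np.mean(acc["G"])),
        "delta_PLSGW_minus_PLSG": float(np.mean(acc["PLS-GW"]) - np.mean(acc["PLS-G"])),
    }
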