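"""Headline simulation studies: recovery, calibration, validation direction.

These functions bundle the package's end-to-end experiments at the study's
conditions so they can be run identically from the test suite and from the
reproduction script.  Each returns plain dicts of numbers computed from
scratch at call time.

Problem sizes: parameter recovery runs at the study scale (264 accessions x
12 environments, 20 seeds); null calibration of the likelihood-ratio test
uses 200 small instances (30 accessions x 6 environments) where the
chi-square reference is the question, not the scale; the cross-validation
direction study runs at 120 accessions x 8 environments, a reduced scale
that keeps per-fold REML refits cheap while preserving the fold structure.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import gwas as gwas_mod
from .genomics import (additive_kernel, dominance_kernel, estimate_frequencies,
                       filter_markers, genetic_clusters, impute_missing,
                       principal_components)
from .envs import build_windows, env_kernel, rn_features
from .reml import lrt, reml_fit, stage2_terms
from .simulate import (complete_design, simulate_population, simulate_stage2,
                       simulate_weather)
from .validation import make_genetic_folds, run_cv

__all__ = [
    "build_panel",
    "recovery_study",
    "null_lrt_study",
    "gwas_null_pvalues",
    "cv_direction_study",
]

VC_NAMES = ("A", "Env", "AxEnv", "D", "DxEnv", "residual")

#: generating variance fractions for the recovery study (additive-dominated,
#: both interaction channels active, as the variance decompositions of
#: seasonal yield suggest)
RECOVERY_VC = {"A": 0.35, "Env": 0.02, "AxEnv": 0.18, "D": 0.15,
               "DxEnv": 0.17, "residual": 0.15}


def build_panel(n_accessions, countries, n_markers=600, divergence=0.03,
                seed=0, years=(2015, 2016)):
    """Simulated genotype panel + kernels for a complete design."""
    design = complete_design(n_accessions, countries=countries,
                             years=list(years))
    depths, _, _ = simulate_population(
        n_accessions, n_markers, n_subpops=10, divergence=divergence,
        depth_mean=40, seed=seed, accession_labels=design.accessions)
    freq = impute_missing(filter_markers(depths, estimate_frequencies(depths))[0])
    G_A = additive_kernel(freq)
    G_D = dominance_kernel(freq)
    weather = simulate_weather(design, seed=seed + 1)
    windows = build_windows("TDM3", max(years))
    harvest_years = {c.name: list(years) for c in design.countries}
    E = env_kernel(rn_features(weather, windows, harvest_years,
                               ["tmean", "tmin", "tmax", "precipitation",
                                "radiation", "humidity", "wind"]))
    return {"design": design, "freq": freq, "G_A": G_A, "G_D": G_D, "E": E}


def recovery_study(n_seeds: int = 20, n_accessions: int = 264,
                   seed: int = 0) -> dict:
    """M3 variance-fraction recovery at the study scale.

    Simulates stage-2 observations from the M3 covariance structure over the
    full 6-country x 2-year grid and refits M3 by REML; reports the mean
    estimated fraction per component over seeds and the largest absolute
    deviation from the generating fractions.
    """
    panel = build_panel(n_accessions,
                        ["Norway", "Estonia", "Sweden", "Lithuania",
                         "Iceland", "Denmark"], seed=seed)
    terms = stage2_terms(panel["G_A"], panel["E"], panel["G_D"], "M3")
    true_frac = np.array([RECOVERY_VC[k] for k in VC_NAMES])
    fracs = []
    for s in range(n_seeds):
        y, idx, _ = simulate_stage2(panel["design"], "TDM3", panel["G_A"],
                                    panel["E"], panel["G_D"],
                                    varcomp=RECOVERY_VC, seed=seed * 10_000 + s)
        fit = reml_fit(y, idx[["accession", "environment"]], terms, model="M3")
        est = np.array([fit.varcomp[k] for k in VC_NAMES])
        fracs.append(est / est.sum())
    mean_frac = np.mean(fracs, axis=0)
    return {"mean_fractions": dict(zip(VC_NAMES, mean_frac)),
            "true_fractions": dict(zip(VC_NAMES, true_frac)),
            "max_abs_error": float(np.abs(mean_frac - true_frac).max()),
            "n_seeds": n_seeds}


def null_lrt_study(n_seeds: int = 200, n_accessions: int = 30,
                   seed: int = 0, alpha: float = 0.05) -> dict:
    """Type-I error of the M1-vs-M2 likelihood-ratio test under M1 data.

    The plain chi-square reference is conservative for a variance component
    on the boundary, so the rejection rate should sit at or below nominal.
    """
    panel = build_panel(n_accessions, ["Norway", "Estonia", "Sweden"],
                        n_markers=300, seed=seed + 7)
    t1 = stage2_terms(panel["G_A"], panel["E"], model="M1")
    t2 = stage2_terms(panel["G_A"], panel["E"], model="M2")
    vc_null = {"A": 0.4, "Env": 0.1, "AxEnv": 0.0, "D": 0.0, "DxEnv": 0.0,
               "residual": 0.5}
    rejections = 0
    for s in range(n_seeds):
        y, idx, _ = simulate_stage2(panel["design"], "TDM3", panel["G_A"],
                                    panel["E"], None, varcomp=vc_null,
                                    seed=seed * 10_000 + s)
        sub = idx[["accession", "environment"]]
        f1 = reml_fit(y, sub, t1, model="M1")
        f2 = reml_fit(y, sub, t2, model="M2")
        if lrt(f1, f2).pvalue < alpha:
            rejections += 1
    rate = rejections / n_seeds
    return {"rejection_rate": rate, "n_seeds": n_seeds, "alpha": alpha,
            "bound": alpha + 2 * np.sqrt(alpha * (1 - alpha) / n_seeds)}


def gwas_null_pvalues(n_seeds: int = 4, n_accessions: int = 60,
                      n_markers: int = 250, seed: int = 0) -> dict:
    """Marginal and conditional scan p-values under the scans' own null.

    Phenotypes are drawn from the GWAS null model itself — polygenic
    additive and dominance effects, polygenic genotype x country effects,
    iid country-year environment effects and residual noise, with no fixed
    single-marker effect and no fixed SNP x country deviation — so both
    scans' p-values should be uniform.  The polygenic G x C variances are
    kept away from zero: random genotype-by-country variation is part of
    the null model (the conditional scan's null hypothesis concerns the
    fixed deviation delta of one marker, not the polygenic interaction),
    and truth-zero components sit on the REML boundary where the adaptive
    variance estimates make the Wald test mildly conservative.
    """
    panel = build_panel(n_accessions, ["Norway", "Estonia", "Sweden",
                                       "Denmark"], n_markers=n_markers,
                        seed=seed + 19)
    pcs, _ = principal_components(panel["freq"], 3)
    design = panel["design"]
    _, idx, _ = simulate_stage2(design, "TDM3", panel["G_A"], panel["E"],
                                panel["G_D"], seed=0)
    vc = {"A": 0.3, "D": 0.1, "AxC": 0.1, "DxC": 0.05, "Env": 0.05,
          "residual": 0.4}
    n = panel["G_A"].n
    ia = panel["G_A"].indices(idx["accession"])
    wa, Va = np.linalg.eigh(panel["G_A"].values)
    La = Va * np.sqrt(np.maximum(wa, 0))
    wd, Vd = np.linalg.eigh(panel["G_D"].values)
    Ld = Vd * np.sqrt(np.maximum(wd, 0))
    env_codes = idx["environment"].astype("category").cat.codes.to_numpy()
    ctry_codes = idx["country"].astype("category").cat.codes.to_numpy()
    n_countries = ctry_codes.max() + 1
    p_marg, p_cond = [], []
    for s in range(n_seeds):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 77, s]))
        a = np.sqrt(vc["A"]) * (La @ rng.standard_normal(n))
        d = np.sqrt(vc["D"]) * (Ld @ rng.standard_normal(n))
        ac = np.sqrt(vc["AxC"]) * (La @ rng.standard_normal((n, n_countries)))
        dc = np.sqrt(vc["DxC"]) * (Ld @ rng.standard_normal((n, n_countries)))
        e = np.sqrt(vc["Env"]) * rng.standard_normal(env_codes.max() + 1)
        y = (a[ia] + d[ia] + ac[ia, ctry_codes] + dc[ia, ctry_codes]
             + e[env_codes]
             + np.sqrt(vc["residual"]) * rng.standard_normal(len(idx)))
        null = gwas_mod.build_null_model(y, idx, pcs, panel["G_A"],
                                         panel["G_D"])
        p_marg += gwas_mod.marginal_scan(null, panel["freq"], idx, y
                                         )["p"].dropna().tolist()
        p_cond += gwas_mod.conditional_scan(null, panel["freq"], idx, y
                                            )["p"].dropna().tolist()
    ks_m = stats.kstest(p_marg, "uniform")
    ks_c = stats.kstest(p_cond, "uniform")
    return {"ks_p_marginal": float(ks_m.pvalue),
            "ks_p_conditional": float(ks_c.pvalue),
            "n_pvalues": len(p_marg)}


def cv_direction_study(n_seeds: int = 5, n_accessions: int = 120,
                       seed: int = 0) -> dict:
    """Does modeling GxE help when the signal is mostly interaction?

    Simulates strong additive x environment variance with weak main additive
    signal over 8 environments, runs leave-one-genetic-cluster-out
    cross-validation for M1 and M2, and reports the paired fold-level
    difference in prediction accuracy (mean and standard error).
    """
    panel = build_panel(n_accessions, ["Norway", "Estonia", "Sweden",
                                       "Lithuania"], n_markers=500,
                        divergence=0.03, seed=seed + 31)
    vc = {"A": 0.10, "Env": 0.05, "AxEnv": 0.30, "D": 0.0, "DxEnv": 0.0,
          "residual": 0.55}
    clusters = genetic_clusters(panel["freq"], k=10)
    t1 = stage2_terms(panel["G_A"], panel["E"], model="M1")
    t2 = stage2_terms(panel["G_A"], panel["E"], model="M2")
    diffs, pa1, pa2 = [], [], []
    for s in range(n_seeds):
        y, idx, _ = simulate_stage2(panel["design"], "TDM3", panel["G_A"],
                                    panel["E"], None, varcomp=vc,
                                    seed=seed * 10_000 + s)
        sub = idx[["accession", "environment", "country"]]
        folds = make_genetic_folds(sub, clusters)
        cv1 = run_cv(y, sub, t1, folds, model="M1")
        cv2 = run_cv(y, sub, t2, folds, model="M2")
        merged = cv1.per_fold.merge(cv2.per_fold, on="fold",
                                    suffixes=("_m1", "_m2")).dropna()
        diffs += (merged["r_m2"] - merged["r_m1"]).tolist()
        pa1.append(cv1.mean_accuracy)
        pa2.append(cv2.mean_accuracy)
    diffs = np.asarray(diffs)
    se = diffs.std(ddof=1) / np.sqrt(len(diffs))
    return {"pa_m1": float(np.mean(pa1)), "pa_m2": float(np.mean(pa2)),
            "mean_paired_diff": float(diffs.mean()),
            "paired_se": float(se), "n_folds": len(diffs)}
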