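"""Per-location spatial mixed models -> z-scaled accession means.

Plot records from one trial site are regressed on accession (fixed), year
(random), accession x year (random), iid trial/replicate blocks, and random
row and column effect vectors with first-order autoregressive (AR1)
correlation over the field indices, nested in year, trial or replicate
according to the site's experimental design.  The AR1 correlations are
estimated by profiling the restricted likelihood over a bounded grid with a
local polish, which is robust for small trials where joint optimization of
correlations and variances is fragile.

Accession means per year are the sum of the fixed accession estimate (on the
observed scale, i.e. including the intercept) and the accession x year BLUP.
They are then z-scaled within each country x year environment using the mean
and standard deviation of the core accessions scored everywhere, which
removes management/scale differences between environments (and with them,
scale-type GxE).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .reml import DenseTerm, ModelFit, reml_fit

__all__ = [
    "SpatialSpec",
    "Stage1Fit",
    "ar1_correlation",
    "fit_stage1",
    "accession_year_means",
    "zscale_core",
]


def ar1_correlation(rho: float, m: int) -> np.ndarray:
    """AR1 correlation matrix: entry (i, j) = rho^|i-j|."""
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    if m < 1:
        raise ValueError("dimension must be >= 1")
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


@dataclass
class SpatialSpec:
    """Random-term layout for one country's trials.

    ``iid_terms``: which block effects enter as iid random terms ("trial"
    and/or "replicate"); ``ar1_nesting``: the level within which the AR1 row
    and column vectors live ("year", "trial" or "replicate").  Differences in
    experimental design between countries are expressed purely through this
    configuration.
    """

    iid_terms: tuple = ("trial",)
    ar1_nesting: str = "trial"
    include_ar1: bool = True
    rho_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(-0.9, 0.91, 0.15), 10))

    def __post_init__(self):
        bad = [t for t in self.iid_terms if t not in ("trial", "replicate")]
        if bad:
            raise ValueError(f"unknown iid terms {bad}")
        if self.ar1_nesting not in ("year", "trial", "replicate"):
            raise ValueError("ar1_nesting must be year, trial or replicate")


@dataclass
class Stage1Fit:
    """REML solution of the per-location spatial model."""

    country: str
    accessions: list
    varcomp: dict
    rho_row: float
    rho_col: float
    loglik: float
    accession_effects: pd.Series       # observed scale: intercept + effect
    acc_year_blup: pd.DataFrame        # accession x year interaction BLUPs
    fit: ModelFit = field(repr=False)
    converged: bool = True
    message: str = ""


def _equality_kernel(keys: pd.Series) -> np.ndarray:
    codes = pd.factorize(keys)[0]
    return (codes[:, None] == codes[None, :]).astype(float)


def _ar1_obs_kernel(group_codes: np.ndarray, pos: np.ndarray, rho: float
                    ) -> np.ndarray:
    same = group_codes[:, None] == group_codes[None, :]
    return same * (rho ** np.abs(pos[:, None] - pos[None, :]))


def _nesting_key(plots: pd.DataFrame, nesting: str) -> pd.Series:
    cols = {"year": ["year"], "trial": ["year", "trial"],
            "replicate": ["year", "replicate"]}[nesting]
    return plots[cols].astype(str).agg("|".join, axis=1)


def fit_stage1(plots: pd.DataFrame, spec: Optional[SpatialSpec] = None
               ) -> Stage1Fit:
    """Fit the spatial mixed model for one country's plot records."""
    spec = spec or SpatialSpec()
    countries = plots["country"].unique()
    if len(countries) != 1:
        raise ValueError("fit_stage1 handles one country at a time; "
                         f"got {list(countries)}")
    plots = plots.reset_index(drop=True)
    if len(plots) < 2:
        raise ValueError("need at least 2 plot observations")
    y = plots["value"].to_numpy(dtype=float)
    accs = sorted(plots["accession"].unique())
    L = len(accs)
    apos = {a: i for i, a in enumerate(accs)}
    ai = plots["accession"].map(apos).to_numpy()

    # sum-to-zero accession contrasts: effect of last level = -sum(others)
    X = np.ones((len(plots), L))
    X[:, 1:] = 0.0
    for j in range(L - 1):
        X[ai == j, j + 1] = 1.0
    X[ai == L - 1, 1:] = -1.0
    fixed_names = ["intercept"] + [f"acc:{a}" for a in accs[:-1]]

    idx = plots.rename(columns={"accession": "accession"}).assign(
        environment=plots["year"].astype(str))[["accession", "environment"]]

    year_key = plots["year"].astype(str)
    accyear_key = plots["accession"].astype(str) + "|" + year_key
    base_terms = [DenseTerm("year", _equality_kernel(year_key)),
                  DenseTerm("acc_year", _equality_kernel(accyear_key))]
    for t in spec.iid_terms:
        key = plots["year"].astype(str) + "|" + plots[t].astype(str)
        base_terms.append(DenseTerm(t, _equality_kernel(key)))

    if spec.include_ar1:
        gkey = pd.factorize(_nesting_key(plots, spec.ar1_nesting))[0]
        rows = plots["row"].to_numpy(dtype=float)
        cols = plots["col"].to_numpy(dtype=float)

        warm = {"init": None}

        def fit_at(rho_row, rho_col):
            terms = base_terms + [
                DenseTerm("row_ar1", _ar1_obs_kernel(gkey, rows, rho_row)),
                DenseTerm("col_ar1", _ar1_obs_kernel(gkey, cols, rho_col)),
            ]
            f = reml_fit(y, idx, terms, X=X, fixed_names=fixed_names,
                         model="stage1", init=warm["init"])
            warm["init"] = np.maximum(
                np.array([f.varcomp[t.name] for t in terms] + [f.varcomp["residual"]]),
                1e-8 * max(np.var(y), 1e-12))
            return f

        # coordinate-wise grid profiling of the AR1 correlations
        best = (0.0, 0.0)
        best_fit = fit_at(*best)
        for sweep in range(2):
            for coord in (0, 1):
                for r in spec.rho_grid:
                    cand = (r, best[1]) if coord == 0 else (best[0], r)
                    if cand == best:
                        continue
                    f = fit_at(*cand)
                    if f.loglik > best_fit.loglik + 1e-10:
                        best, best_fit = cand, f
        # local polish
        res = optimize.minimize(
            lambda r: -fit_at(*np.clip(r, -0.97, 0.97)).loglik,
            x0=np.array(best), method="Nelder-Mead",
            options={"xatol": 5e-3, "fatol": 1e-7, "maxfev": 60})
        polished = tuple(np.clip(res.x, -0.97, 0.97))
        f = fit_at(*polished)
        if f.loglik >= best_fit.loglik:
            best, best_fit = polished, f
        rho_row, rho_col = best
        fit = best_fit
        converged = fit.converged
        message = fit.message
    else:
        fit = reml_fit(y, idx, base_terms, X=X, fixed_names=fixed_names,
                       model="stage1")
        rho_row = rho_col = 0.0
        converged, message = fit.converged, fit.message

    beta = fit.beta
    eff = np.empty(L)
    eff[: L - 1] = beta[1:L]
    eff[L - 1] = -beta[1:L].sum()
    accession_effects = pd.Series(beta[0] + eff, index=accs)

    # accession x year BLUPs: sigma2 * Z' P y per (accession, year) cell
    s2 = fit.varcomp["acc_year"]
    cells = pd.DataFrame({"accession": plots["accession"],
                          "year": plots["year"], "py": fit.py})
    agg = cells.groupby(["accession", "year"])["py"].sum() * s2
    blup = agg.unstack("year")

    return Stage1Fit(country=str(countries[0]), accessions=accs,
                     varcomp=fit.varcomp, rho_row=float(rho_row),
                     rho_col=float(rho_col), loglik=fit.loglik,
                     accession_effects=accession_effects,
                     acc_year_blup=blup, fit=fit,
                     converged=converged, message=message)


def accession_year_means(fit: Stage1Fit) -> pd.DataFrame:
    """Raw accession means per year: fixed accession effect + acc x year BLUP.

    Cells where an accession was never scored in a year are absent (NaN),
    never imputed.
    """
    eff = fit.accession_effects
    blup = fit.acc_year_blup.reindex(eff.index)
    means = blup.add(eff, axis=0)
    means.index.name = "accession"
    means.columns.name = "year"
    return means


def zscale_core(means_by_country: dict, core_ids: Sequence[str]
                ) -> pd.DataFrame:
    """Z-scale raw accession-year means per environment on the core collection.

    ``means_by_country`` maps country name to an accession x year DataFrame
    of raw means.  For each country-year environment the core accessions'
    mean and standard deviation (n-1 denominator) are used to center and
    scale all accessions.  Returns the long stage-2 table with columns
    accession, country, year, environment, raw, scaled, is_core.
    """
    core = set(core_ids)
    rows = []
    for country, means in means_by_country.items():
        for year in means.columns:
            col = means[year].dropna()
            core_vals = col[col.index.isin(core)]
            if len(core_vals) < 2:
                raise ValueError(f"{country}-{year}: fewer than 2 core accessions")
            mu, sd = core_vals.mean(), core_vals.std(ddof=1)
            if sd == 0:
                raise ValueError(f"{country}-{year}: zero core standard deviation")
            for acc, raw in col.items():
                rows.append((acc, country, year, f"{country}-{year}",
                             raw, (raw - mu) / sd, acc in core))
    return pd.DataFrame(rows, columns=["accession", "country", "year",
                                       "environment", "raw", "scaled",
                                       "is_core"])
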