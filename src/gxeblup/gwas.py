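"""Marginal and conditional association scans on stage-2 accession means.

The null (SNP-free) mixed model carries the fixed effects of the intercept,
the first three genomic principal components (population structure) and
country (sum-to-zero), plus random additive and dominance effects, their
interactions with country (G (x) I covariance over countries), an iid
country-year environment effect (present only for traits scored in more than
one year per country), and a residual.

The marginal scan adds the accession's alternate-allele frequency s_i as a
fixed covariate and Wald-tests its effect alpha (df 1): QTL with consistent
effects across environments.  The conditional scan adds s_i x country
deviations delta_j under a sum-to-zero constraint, so alpha stays the
across-country average effect, and jointly Wald-tests the deviation vector
(df = n_countries - 1): environment-dependent QTL.  Variance components are
estimated once under the null and held fixed across markers
(population-parameters-previously-determined style); generalized least
squares under the null covariance gives each marker's effects and standard
errors.  Multiple testing is controlled by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import stats

from .genomics import FrequencyMatrix
from .kernels import Kernel
from .reml import DenseTerm, ModelFit, reml_fit

__all__ = [
    "GWASNullModel",
    "build_null_model",
    "marginal_scan",
    "conditional_scan",
    "fdr_adjust",
    "genomic_control_lambda",
]


@dataclass
class GWASNullModel:
    """SNP-free mixed model: fixed design, REML components, GLS machinery."""

    fit: ModelFit
    X0: np.ndarray = field(repr=False)
    fixed_names: list = field(default_factory=list)
    countries: list = field(default_factory=list)
    country_codes: np.ndarray = field(default=None, repr=False)
    has_env_term: bool = False
    _cho: tuple = field(default=None, repr=False)

    @property
    def varcomp(self) -> dict:
        return self.fit.varcomp

    def whiten(self, M: np.ndarray) -> np.ndarray:
        """V^{-1/2} M via the Cholesky factor of the null covariance."""
        return sla.solve_triangular(self._cho, M, lower=True, check_finite=False)


def _sum_to_zero(codes: np.ndarray, k: int) -> np.ndarray:
    """k-1 sum-to-zero contrast columns for a factor with k levels."""
    Z = np.zeros((len(codes), k - 1))
    for j in range(k - 1):
        Z[codes == j, j] = 1.0
    Z[codes == k - 1, :] = -1.0
    return Z


def build_null_model(
    y,
    index: pd.DataFrame,
    pcs: pd.DataFrame,
    G_A: Kernel,
    G_D: Optional[Kernel] = None,
) -> GWASNullModel:
    """Fit the SNP-free GWAS mixed model by REML.

    ``index`` needs accession, environment, country and year columns; the
    iid environment (country-year) term is included only when at least one
    country is scored in more than one year for the trait.
    """
    y = np.asarray(y, dtype=float)
    for col in ("accession", "environment", "country", "year"):
        if col not in index.columns:
            raise ValueError(f"index needs a {col!r} column")
    n = len(y)
    countries = sorted(pd.unique(index["country"]))
    ccodes = index["country"].map({c: i for i, c in enumerate(countries)}).to_numpy()
    pcs_mat = pcs.reindex(index["accession"]).to_numpy(dtype=float)
    if np.isnan(pcs_mat).any():
        raise ValueError("accessions missing from the PC score table")

    blocks = [np.ones((n, 1)), pcs_mat]
    names = ["intercept"] + list(pcs.columns)
    if len(countries) > 1:
        blocks.append(_sum_to_zero(ccodes, len(countries)))
        names += [f"country:{c}" for c in countries[:-1]]
    X0 = np.column_stack(blocks)
    if np.linalg.matrix_rank(X0) < X0.shape[1]:
        raise ValueError("rank-deficient fixed design (PCs collinear with country?)")

    ia = G_A.indices(index["accession"])
    Ka = G_A.values[np.ix_(ia, ia)]
    same_country = (ccodes[:, None] == ccodes[None, :]).astype(float)
    terms = [DenseTerm("A", Ka), DenseTerm("AxC", Ka * same_country)]
    if G_D is not None:
        id_ = G_D.indices(index["accession"])
        Kd = G_D.values[np.ix_(id_, id_)]
        terms += [DenseTerm("D", Kd), DenseTerm("DxC", Kd * same_country)]
    years_per_country = index.groupby("country")["year"].nunique()
    has_env = bool((years_per_country > 1).any())
    if has_env:
        ecodes = pd.factorize(index["environment"])[0]
        terms.append(DenseTerm("Env",
                               (ecodes[:, None] == ecodes[None, :]).astype(float)))

    fit = reml_fit(y, index[["accession", "environment"]], terms,
                   X=X0, fixed_names=names, model="gwas-null")
    V = np.zeros((n, n))
    for t in terms:
        V += fit.varcomp[t.name] * t.K
    V[np.diag_indices(n)] += max(fit.varcomp["residual"], 1e-8 * np.var(y))
    cho = np.linalg.cholesky(V)
    return GWASNullModel(fit=fit, X0=X0, fixed_names=names,
                         countries=countries, country_codes=ccodes,
                         has_env_term=has_env, _cho=cho)


def _snp_vector(null: GWASNullModel, freq: FrequencyMatrix, col: int,
                index: pd.DataFrame) -> np.ndarray:
    lookup = pd.Series(freq.p[:, col], index=freq.accessions)
    return index["accession"].map(lookup).to_numpy(dtype=float)


def _gls(null: GWASNullModel, y: np.ndarray, X: np.ndarray):
    """GLS under the null covariance; returns (beta, cov) or None if singular."""
    Xw = null.whiten(X)
    yw = null.whiten(y)
    XtX = Xw.T @ Xw
    sign, _ = np.linalg.slogdet(XtX)
    if sign <= 0 or np.linalg.cond(XtX) > 1e10:
        return None
    cov = np.linalg.inv(XtX)
    beta = cov @ (Xw.T @ yw)
    return beta, cov


def marginal_scan(null: GWASNullModel, freq: FrequencyMatrix,
                  index: pd.DataFrame, y) -> pd.DataFrame:
    """Per-marker Wald test of the environment-independent allele effect."""
    y = np.asarray(y, dtype=float)
    rows = []
    p0 = null.X0.shape[1]
    for col in range(freq.n_markers):
        s = _snp_vector(null, freq, col, index)
        X = np.column_stack([null.X0, s])
        res = _gls(null, y, X)
        mk = freq.markers.iloc[col]
        if res is None:
            rows.append((mk["id"], mk.get("chrom"), mk.get("pos"),
                         np.nan, np.nan, np.nan, 1, np.nan, True))
            continue
        beta, cov = res
        alpha, se = beta[p0], np.sqrt(cov[p0, p0])
        wald = (alpha / se) ** 2
        p = float(stats.chi2.sf(wald, 1))
        rows.append((mk["id"], mk.get("chrom"), mk.get("pos"),
                     alpha, se, wald, 1, p, False))
    out = pd.DataFrame(rows, columns=["id", "chrom", "pos", "alpha", "se",
                                      "wald", "df", "p", "collinear"])
    out["q"] = fdr_adjust(out["p"])
    return out


def conditional_scan(null: GWASNullModel, freq: FrequencyMatrix,
                     index: pd.DataFrame, y) -> pd.DataFrame:
    """Per-marker joint Wald test of SNP x country effect deviations.

    Fits s_i and s_i x country (sum-to-zero) jointly by GLS and tests the
    deviation vector delta (df = n_countries - 1).  Per-country effects
    alpha + delta_j with standard errors from the joint GLS covariance are
    returned for every country.
    """
    y = np.asarray(y, dtype=float)
    C = len(null.countries)
    if C < 2:
        raise ValueError("conditional scan needs >= 2 scored countries")
    p0 = null.X0.shape[1]
    rows = []
    for col in range(freq.n_markers):
        s = _snp_vector(null, freq, col, index)
        SC = _sum_to_zero(null.country_codes, C) * s[:, None]
        X = np.column_stack([null.X0, s, SC])
        res = _gls(null, y, X)
        mk = freq.markers.iloc[col]
        base = [mk["id"], mk.get("chrom"), mk.get("pos")]
        if res is None:
            rows.append(base + [np.nan, np.nan, np.nan, C - 1, np.nan, True]
                        + [np.nan] * (2 * C))
            continue
        beta, cov = res
        alpha, se_a = beta[p0], np.sqrt(cov[p0, p0])
        dsl = slice(p0 + 1, p0 + C)
        delta = beta[dsl]
        cov_d = cov[dsl, dsl]
        try:
            wald = float(delta @ np.linalg.solve(cov_d, delta))
        except np.linalg.LinAlgError:
            rows.append(base + [alpha, se_a, np.nan, C - 1, np.nan, True]
                        + [np.nan] * (2 * C))
            continue
        p = float(stats.chi2.sf(wald, C - 1))
        # per-country effect alpha + delta_j: linear combination L beta
        effs, ses = [], []
        for j in range(C):
            L = np.zeros(len(beta))
            L[p0] = 1.0
            if j < C - 1:
                L[p0 + 1 + j] = 1.0
            else:
                L[dsl] = -1.0
            effs.append(float(L @ beta))
            ses.append(float(np.sqrt(L @ cov @ L)))
        rows.append(base + [alpha, se_a, wald, C - 1, p, False] + effs + ses)
    cols = (["id", "chrom", "pos", "alpha", "se_alpha", "wald", "df", "p",
             "collinear"]
            + [f"effect:{c}" for c in null.countries]
            + [f"se:{c}" for c in null.countries])
    out = pd.DataFrame(rows, columns=cols)
    out["q"] = fdr_adjust(out["p"])
    return out


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (NaN-tolerant)."""
    p = np.asarray(pvals, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum() == 0:
        return q
    ps = p[ok]
    m = len(ps)
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qs = np.empty(m)
    qs[order] = np.minimum(ranked, 1.0)
    q[ok] = qs
    return q


def genomic_control_lambda(pvals) -> float:
    """Median chi-square inflation factor (reported, never applied)."""
    p = np.asarray(pvals, dtype=float)
    p = p[~np.isnan(p)]
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / stats.chi2.ppf(0.5, 1))
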