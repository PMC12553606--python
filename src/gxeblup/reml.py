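"""Multi-kernel Gaussian mixed-model engine.

Fits models of the form

    y = X beta + sum_k u_k + eps,   u_k ~ N(0, sigma2_k K_k),  eps ~ N(0, sigma2_e I)

by restricted maximum likelihood (REML), where each ``K_k`` is an
observation-level covariance built from a genomic kernel, an environmental
kernel, or their Kronecker product restricted to observed accession x
environment cells.  The stage-2 models used for genomic prediction are

    M1: y_ij = mu + a_i + e_j + eps_ij
    M2: M1 + ae_ij          (additive x environment, cov G_A (x) E)
    M3: M2 + d_i + de_ij    (dominance and dominance x environment)

Variance components are maximized by average-information (AI) REML with
step-halving, falling back to quasi-Newton search on the log-variance scale.
When the observations form a complete accession x environment rectangle and
all environment-side matrices commute (which holds whenever the environmental
kernel is built from column-centered features, making its row sums zero), the
observation covariance block-diagonalizes in the eigenbasis of the environment
factor; the engine then works with per-eigencomponent blocks of size
n_accessions, reducing the cost per likelihood evaluation from O((nm)^3) to
O(m n^3).  Both code paths produce identical likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import optimize, stats

from .kernels import Kernel

__all__ = [
    "KronTerm",
    "DenseTerm",
    "ModelFit",
    "LRTResult",
    "stage2_terms",
    "make_index",
    "reml_fit",
    "blup_effects",
    "predict_cells",
    "interaction_covariance",
    "lrt",
    "heritability",
    "restricted_loglik",
]

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# terms and observation index
# ---------------------------------------------------------------------------

@dataclass
class KronTerm:
    """Random effect with covariance ``A (x) B`` over (accession, environment).

    ``kind`` is one of ``"accession"`` (B is all-ones: a main genetic effect),
    ``"environment"`` (A all-ones), or ``"interaction"``.
    """

    name: str
    A: Kernel
    B: Kernel
    kind: str

    def obs_matrix(self, ia: np.ndarray, je: np.ndarray,
                   ia2: Optional[np.ndarray] = None,
                   je2: Optional[np.ndarray] = None) -> np.ndarray:
        if ia2 is None:
            ia2, je2 = ia, je
        return self.A.values[np.ix_(ia, ia2)] * self.B.values[np.ix_(je, je2)]


@dataclass
class DenseTerm:
    """Random effect with an explicit observation-level covariance matrix."""

    name: str
    K: np.ndarray


def make_index(accessions: Sequence, environments: Sequence,
               country: Optional[Sequence] = None,
               year: Optional[Sequence] = None) -> pd.DataFrame:
    """Observation index: one row per stage-2 observation (accession, environment)."""
    df = pd.DataFrame({"accession": list(accessions),
                       "environment": list(environments)})
    if country is not None:
        df["country"] = list(country)
    if year is not None:
        df["year"] = list(year)
    if df.duplicated(["accession", "environment"]).any():
        raise ValueError("duplicate (accession, environment) pairs in index")
    return df


def _ones_kernel(labels) -> Kernel:
    n = len(labels)
    k = Kernel.__new__(Kernel)  # bypass trace validation: J is a design device
    k.values = np.ones((n, n))
    k.labels = list(labels)
    k._pos = {lab: i for i, lab in enumerate(k.labels)}
    return k


MODEL_TERMS = {
    "M1": ("A", "Env"),
    "M2": ("A", "Env", "AxEnv"),
    "M3": ("A", "Env", "AxEnv", "D", "DxEnv"),
}


def stage2_terms(G_A: Kernel, E: Kernel, G_D: Optional[Kernel] = None,
                 model: str = "M3") -> list[KronTerm]:
    """Random-effect terms for stage-2 model M1, M2 or M3."""
    if model not in MODEL_TERMS:
        raise ValueError(f"unknown model tag {model!r}; expected M1, M2 or M3")
    J_acc = _ones_kernel(G_A.labels)
    J_env = _ones_kernel(E.labels)
    pool = {
        "A": KronTerm("A", G_A, J_env, "accession"),
        "Env": KronTerm("Env", J_acc, E, "environment"),
        "AxEnv": KronTerm("AxEnv", G_A, E, "interaction"),
    }
    if G_D is not None:
        pool["D"] = KronTerm("D", G_D, J_env, "accession")
        pool["DxEnv"] = KronTerm("DxEnv", G_D, E, "interaction")
    names = MODEL_TERMS[model]
    missing = [t for t in names if t not in pool]
    if missing:
        raise ValueError(f"model {model} requires a dominance kernel (terms {missing})")
    return [pool[t] for t in names]


def interaction_covariance(K_G: Kernel, K_E: Kernel, index: pd.DataFrame) -> np.ndarray:
    """Observation covariance ``K_G[i,i'] * K_E[j,j']`` for the index's cells.

    Equals the full Kronecker product restricted to the observed
    accession x environment cells (rows/columns of unobserved cells deleted).
    """
    ia = K_G.indices(index["accession"])
    je = K_E.indices(index["environment"])
    return K_G.values[np.ix_(ia, ia)] * K_E.values[np.ix_(je, je)]


# ---------------------------------------------------------------------------
# block-structured likelihood machinery
# ---------------------------------------------------------------------------

class _BlockProblem:
    """REML working representation: independent blocks sharing term matrices.

    Block ``b`` contributes ``V_b = sum_k coeff[k, b] * sigma2[k] * M_k``.
    The dense path uses a single block; the rotated (complete-design) path
    uses one block per eigencomponent of the environment factor.
    """

    def __init__(self, ys, Xs, mats, coeffs, names):
        self.ys = ys                  # list of block response vectors
        self.Xs = Xs                  # list of block fixed-design matrices
        self.mats = mats              # per-term shared matrix (None = identity)
        self.coeffs = np.asarray(coeffs, dtype=float)  # (n_terms, n_blocks)
        self.names = names            # term names, residual last
        self.N = sum(len(y) for y in ys)
        self.p = Xs[0].shape[1]

    def _term_mat(self, k: int, nb: int) -> np.ndarray:
        m = self.mats[k]
        return np.eye(nb) if m is None else m

    def evaluate(self, sigma: np.ndarray, need_grad: bool = True):
        """Restricted log-likelihood and (optionally) gradient + AI matrix."""
        nt = len(self.names)
        p = self.p
        logdetV = 0.0
        Mxx = np.zeros((p, p))
        bxy = np.zeros(p)
        yWy = 0.0
        Ws, WXs, Wys = [], [], []
        for b, (y, X) in enumerate(zip(self.ys, self.Xs)):
            nb = len(y)
            V = np.zeros((nb, nb))
            for k in range(nt):
                c = self.coeffs[k, b] * sigma[k]
                if c == 0.0:
                    continue
                m = self.mats[k]
                if m is None:
                    V[np.diag_indices(nb)] += c
                else:
                    V += c * m
            try:
                cf = sla.cho_factor(V, lower=True, check_finite=False)
            except sla.LinAlgError:
                return None
            logdetV += 2.0 * np.sum(np.log(np.diag(cf[0])))
            W = sla.cho_solve(cf, np.eye(nb), check_finite=False)
            Wy = W @ y
            WX = W @ X
            Ws.append(W); WXs.append(WX); Wys.append(Wy)
            Mxx += X.T @ WX
            bxy += WX.T @ y
            yWy += y @ Wy
        sign, logdetM = np.linalg.slogdet(Mxx)
        if sign <= 0:
            return None
        Minv = np.linalg.inv(Mxx)
        beta = Minv @ bxy
        q = yWy - bxy @ beta
        ll = -0.5 * ((self.N - p) * _LOG2PI + logdetV + logdetM + q)
        us = [Wy - WX @ beta for Wy, WX in zip(Wys, WXs)]
        out = {"ll": ll, "beta": beta, "us": us, "Minv": Minv}
        if not need_grad:
            return out
        # gradient: dl/dsigma2_k = -0.5 [tr(P K_k) - u' K_k u]
        grad = np.zeros(nt)
        vs = [[None] * len(self.ys) for _ in range(nt)]
        for k in range(nt):
            trPK = 0.0
            uKu = 0.0
            xkx = np.zeros((p, p))
            for b in range(len(self.ys)):
                c = self.coeffs[k, b]
                if c == 0.0:
                    vs[k][b] = np.zeros(len(self.ys[b]))
                    continue
                m = self.mats[k]
                W, WX, u = Ws[b], WXs[b], us[b]
                if m is None:
                    trPK += c * np.trace(W)
                    xkx += c * (WX.T @ WX)
                    v = c * u
                else:
                    trPK += c * np.sum(W * m)
                    xkx += c * (WX.T @ m @ WX)
                    v = c * (m @ u)
                uKu += v @ u
                vs[k][b] = v
            trPK -= np.sum(Minv * xkx)
            grad[k] = -0.5 * (trPK - uKu)
        # average information: AI[k,l] = 0.5 v_k' P v_l
        tvec = np.zeros((nt, p))
        for k in range(nt):
            for b in range(len(self.ys)):
                tvec[k] += WXs[b].T @ vs[k][b]
        AI = np.zeros((nt, nt))
        Pv = [[None] * len(self.ys) for _ in range(nt)]
        for k in range(nt):
            corr = Minv @ tvec[k]
            for b in range(len(self.ys)):
                Pv[k][b] = Ws[b] @ vs[k][b] - WXs[b] @ corr
        for k in range(nt):
            for l in range(k, nt):
                a = 0.5 * sum(vs[k][b] @ Pv[l][b] for b in range(len(self.ys)))
                AI[k, l] = AI[l, k] = a
        out["grad"] = grad
        out["AI"] = AI
        return out


def _simultaneous_eigenbasis(Bs: list[np.ndarray], tol: float = 1e-8):
    """Common eigenbasis of commuting symmetric matrices, or None."""
    m = Bs[0].shape[0]
    rng = np.random.default_rng(12345)
    w = rng.uniform(0.5, 1.5, size=len(Bs))
    S = sum(wi * Bi for wi, Bi in zip(w, Bs))
    _, U = np.linalg.eigh((S + S.T) / 2.0)
    diags = []
    for Bi in Bs:
        R = U.T @ Bi @ U
        off = R - np.diag(np.diag(R))
        if np.abs(off).max() > tol * max(1.0, np.abs(R).max()):
            return None
        diags.append(np.diag(R).copy())
    return U, diags


def _build_problem(y, X, index, terms):
    """Choose the rotated (complete-design) or dense representation."""
    y = np.asarray(y, dtype=float)
    n_obs = len(y)
    all_kron = all(isinstance(t, KronTerm) for t in terms)
    if all_kron:
        accs = list(pd.unique(index["accession"]))
        envs = list(pd.unique(index["environment"]))
        n, m = len(accs), len(envs)
        if n * m == n_obs and m >= 2:
            apos = {a: i for i, a in enumerate(accs)}
            epos = {e: j for j, e in enumerate(envs)}
            ii = index["accession"].map(apos).to_numpy()
            jj = index["environment"].map(epos).to_numpy()
            flat = ii * m + jj
            if len(np.unique(flat)) == n_obs:
                A_subs = [t.A.values[np.ix_(t.A.indices(accs), t.A.indices(accs))]
                          for t in terms]
                B_subs = [t.B.values[np.ix_(t.B.indices(envs), t.B.indices(envs))]
                          for t in terms]
                basis = _simultaneous_eigenbasis(B_subs)
                if basis is not None:
                    U, diags = basis
                    Ygrid = np.empty((n, m)); Ygrid[ii, jj] = y
                    Yrot = Ygrid @ U
                    Xrot = np.empty((n, m, X.shape[1]))
                    for c in range(X.shape[1]):
                        Xg = np.empty((n, m)); Xg[ii, jj] = X[:, c]
                        Xrot[:, :, c] = Xg @ U
                    ys = [Yrot[:, r] for r in range(m)]
                    Xs = [Xrot[:, r, :] for r in range(m)]
                    mats = A_subs + [None]
                    coeffs = np.zeros((len(terms) + 1, m))
                    for k in range(len(terms)):
                        coeffs[k] = diags[k]
                    coeffs[-1] = 1.0
                    prob = _BlockProblem(ys, Xs, mats, coeffs,
                                         [t.name for t in terms] + ["residual"])
                    prob._rotation = (U, ii, jj, n, m)
                    return prob
    # dense fall-back
    mats = []
    for t in terms:
        if isinstance(t, KronTerm):
            ia = t.A.indices(index["accession"])
            je = t.B.indices(index["environment"])
            mats.append(t.obs_matrix(ia, je))
        else:
            K = np.asarray(t.K, dtype=float)
            if K.shape != (n_obs, n_obs):
                raise ValueError(f"dense term {t.name!r} has shape {K.shape}, "
                                 f"expected ({n_obs}, {n_obs})")
            mats.append(K)
    mats.append(None)
    coeffs = np.ones((len(terms) + 1, 1))
    prob = _BlockProblem([y], [X], mats, coeffs,
                         [t.name for t in terms] + ["residual"])
    prob._rotation = None
    return prob


def _obs_order(prob, blocks_vec):
    """Map per-block vectors back to the original observation order."""
    if prob._rotation is None:
        return blocks_vec[0]
    U, ii, jj, n, m = prob._rotation
    grid = np.column_stack(blocks_vec) @ U.T
    return grid[ii, jj]


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """REML solution of a multi-kernel mixed model."""

    model: str
    beta: np.ndarray
    fixed_names: list
    varcomp: dict
    loglik: float
    converged: bool
    n_iter: int
    index: pd.DataFrame = field(repr=False)
    terms: list = field(repr=False)
    y: np.ndarray = field(repr=False)
    X: np.ndarray = field(repr=False)
    py: np.ndarray = field(repr=False)      # P y = V^{-1}(y - X beta)
    message: str = ""

    @property
    def mu(self) -> float:
        return float(self.beta[0])

    @property
    def n_components(self) -> int:
        return len(self.varcomp)

    def fitted_components(self) -> pd.DataFrame:
        """Observation-level contribution of each random term (sigma2_k K_k P y)."""
        cols = {}
        for t in self.terms:
            s2 = self.varcomp[t.name]
            if isinstance(t, KronTerm):
                ia = t.A.indices(self.index["accession"])
                je = t.B.indices(self.index["environment"])
                K = t.obs_matrix(ia, je)
            else:
                K = t.K
            cols[t.name] = s2 * (K @ self.py)
        return pd.DataFrame(cols, index=self.index.index)

    def fitted_values(self) -> np.ndarray:
        comp = self.fitted_components()
        return self.X @ self.beta + comp.to_numpy().sum(axis=1)


@dataclass
class LRTResult:
    """Likelihood-ratio test between nested REML fits."""

    lr: float
    df: int
    pvalue: float


# ---------------------------------------------------------------------------
# REML driver
# ---------------------------------------------------------------------------

def reml_fit(
    y,
    index: pd.DataFrame,
    terms: Sequence,
    X: Optional[np.ndarray] = None,
    fixed_names: Optional[list] = None,
    model: str = "",
    init: Optional[np.ndarray] = None,
    optimize_vc: bool = True,
    max_iter: int = 200,
    tol: float = 1e-8,
    n_starts: int = 1,
    seed: int = 0,
) -> ModelFit:
    """Fit a multi-kernel mixed model by AI-REML.

    Parameters
    ----------
    y
        Observation vector (stage-2 accession means, z-scaled).
    index
        DataFrame with ``accession`` and ``environment`` columns, one row
        per observation, aligned with ``y``.
    terms
        Random-effect terms (:class:`KronTerm` / :class:`DenseTerm`); the
        iid residual is always added implicitly.
    X
        Fixed-effect design; defaults to an intercept-only column.
    init
        Starting variance components (terms + residual); defaults to an
        equal split of Var(y).
    optimize_vc
        If False, evaluate at ``init`` without optimizing (used for
        fixed-component predictions and likelihood checks).
    """
    y = np.asarray(y, dtype=float).ravel()
    n_obs = len(y)
    if len(index) != n_obs:
        raise ValueError("index length does not match y")
    if X is None:
        X = np.ones((n_obs, 1))
        fixed_names = fixed_names or ["intercept"]
    else:
        X = np.asarray(X, dtype=float)
        fixed_names = fixed_names or [f"x{i}" for i in range(X.shape[1])]
    if optimize_vc and n_obs < 10:
        raise ValueError("REML optimization requires at least 10 observations")
    nt = len(terms) + 1
    vary = float(np.var(y, ddof=1)) if n_obs > 1 else 1.0
    if vary <= 0:
        vary = 1.0
    # the floor keeps V invertible in exact-fit limits (cond <= ~cap/floor)
    floor = 1e-8 * vary
    prob = _build_problem(y, X, index, terms)

    if init is None:
        sigma0 = np.full(nt, vary / nt)
    else:
        sigma0 = np.maximum(np.asarray(init, dtype=float), floor)
        if len(sigma0) != nt:
            raise ValueError(f"init must have {nt} entries (terms + residual)")

    if not optimize_vc:
        ev = prob.evaluate(sigma0, need_grad=False)
        if ev is None:
            raise np.linalg.LinAlgError("singular covariance at supplied components")
        return _finalize(prob, sigma0, ev, model, fixed_names, index, terms,
                         y, X, floor, True, 0, "fixed components")

    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, n_starts)):
        s0 = sigma0 if start == 0 else sigma0 * rng.uniform(0.3, 3.0, size=nt)
        res = _ai_reml(prob, s0, floor, vary, max_iter, tol)
        if res is not None and (best is None or res[2]["ll"] > best[2]["ll"]):
            best = res
    if best is None:
        raise RuntimeError("REML failed to evaluate the likelihood at any start")
    sigma, info, ev = best
    return _finalize(prob, sigma, ev, model, fixed_names, index, terms, y, X,
                     floor, info["converged"], info["n_iter"], info["message"])


def _ai_reml(prob, sigma0, floor, vary, max_iter, tol):
    cap = 1e3 * vary
    sigma = np.clip(sigma0.copy(), floor, cap)
    ev = prob.evaluate(sigma)
    if ev is None:
        sigma = np.maximum(sigma, 1e-4 * vary)
        ev = prob.evaluate(sigma)
        if ev is None:
            return None
    converged = False
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        grad, AI = ev["grad"], ev["AI"]
        free = ~((sigma <= floor * 1.01) & (grad < 0.0))
        if not np.any(free):
            converged = True
            break
        delta = np.zeros_like(sigma)
        Af = AI[np.ix_(free, free)]
        Af = Af + 1e-8 * max(1.0, np.abs(np.diag(Af)).max()) * np.eye(Af.shape[0])
        try:
            delta[free] = np.linalg.solve(Af, grad[free])
        except np.linalg.LinAlgError:
            delta[free] = grad[free] / np.maximum(np.diag(AI)[free], 1e-8)
        step = 1.0
        improved = False
        for _ in range(30):
            cand = np.clip(sigma + step * delta, floor, cap)
            ev_new = prob.evaluate(cand)
            if ev_new is not None and ev_new["ll"] >= ev["ll"] - 1e-12:
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        dll = ev_new["ll"] - ev["ll"]
        sigma, ev = cand, ev_new
        if abs(dll) < tol * (1.0 + abs(ev["ll"])):
            converged = True
            break
    msg = "converged" if converged else "AI-REML did not converge; quasi-Newton fallback"
    if not converged:
        # fall back to L-BFGS-B on log variance components
        def negll(logs):
            s = np.exp(logs)
            e = prob.evaluate(s)
            if e is None:
                return 1e12, np.zeros_like(logs)
            return -e["ll"], -(e["grad"] * s)
        lb = np.log(floor)
        ub = np.log(cap)
        res = optimize.minimize(negll, np.log(np.maximum(sigma, floor)),
                                jac=True, method="L-BFGS-B",
                                bounds=[(lb, ub)] * len(sigma),
                                options={"maxiter": 500, "ftol": 1e-12})
        s_alt = np.exp(res.x)
        ev_alt = prob.evaluate(s_alt)
        if ev_alt is not None and ev_alt["ll"] >= ev["ll"]:
            sigma, ev = s_alt, ev_alt
            converged = res.success
            msg = "converged (quasi-Newton fallback)" if converged else res.message
    return sigma, {"converged": converged, "n_iter": n_iter, "message": msg}, ev


def _finalize(prob, sigma, ev, model, fixed_names, index, terms, y, X, floor,
              converged, n_iter, message):
    py = _obs_order(prob, ev["us"])
    names = [t.name for t in terms] + ["residual"]
    varcomp = {}
    for nm, s in zip(names, sigma):
        varcomp[nm] = 0.0 if s <= floor * 1.5 else float(s)
    return ModelFit(model=model, beta=ev["beta"], fixed_names=list(fixed_names),
                    varcomp=varcomp, loglik=float(ev["ll"]), converged=converged,
                    n_iter=n_iter, index=index.reset_index(drop=True), terms=list(terms),
                    y=y, X=X, py=py, message=message)


def restricted_loglik(y, index, terms, sigma, X: Optional[np.ndarray] = None) -> float:
    """Restricted log-likelihood at a given variance-component vector."""
    y = np.asarray(y, dtype=float).ravel()
    if X is None:
        X = np.ones((len(y), 1))
    prob = _build_problem(y, np.asarray(X, dtype=float), index, terms)
    ev = prob.evaluate(np.asarray(sigma, dtype=float), need_grad=False)
    if ev is None:
        return -np.inf
    return float(ev["ll"])


# ---------------------------------------------------------------------------
# BLUPs, prediction, tests
# ---------------------------------------------------------------------------

def blup_effects(fit: ModelFit) -> dict:
    """Latent effect BLUPs per component at the REML optimum.

    Returns a dict mapping term name to a Series (accession- or
    environment-indexed main effects) or DataFrame (accession x environment
    interaction effects).  Effects are the conditional means
    ``sigma2_k K_k Z' V^{-1}(y - X beta)`` over the term's full label set, so
    accessions/environments outside the training data get genomic/enviromic
    extrapolations.
    """
    out = {}
    py = fit.py
    for t in fit.terms:
        if not isinstance(t, KronTerm):
            raise ValueError(f"term {t.name!r} has no latent Kronecker structure")
        s2 = fit.varcomp[t.name]
        ia = t.A.indices(fit.index["accession"])
        je = t.B.indices(fit.index["environment"])
        if t.kind == "accession":
            # B is all-ones: collapse observations per accession
            w = np.zeros(t.A.n)
            np.add.at(w, ia, py)
            out[t.name] = pd.Series(s2 * (t.A.values @ w), index=t.A.labels)
        elif t.kind == "environment":
            w = np.zeros(t.B.n)
            np.add.at(w, je, py)
            out[t.name] = pd.Series(s2 * (t.B.values @ w), index=t.B.labels)
        else:
            M = np.zeros((t.A.n, t.B.n))
            np.add.at(M, (ia, je), py)
            out[t.name] = pd.DataFrame(s2 * (t.A.values @ M @ t.B.values),
                                       index=t.A.labels, columns=t.B.labels)
    return out


def predict_cells(fit: ModelFit, new_index: pd.DataFrame,
                  X_new: Optional[np.ndarray] = None,
                  allow_overlap: bool = False) -> pd.DataFrame:
    """Predict unobserved accession x environment cells.

    Joint-Gaussian conditional mean ``X_new beta + C_new,obs V^{-1}(y - X beta)``
    where ``C`` is assembled from the fit's variance components and kernels.
    Per-component contributions are returned alongside the total.
    """
    if not allow_overlap:
        seen = set(zip(fit.index["accession"], fit.index["environment"]))
        clash = [c for c in zip(new_index["accession"], new_index["environment"])
                 if c in seen]
        if clash:
            raise ValueError(f"new cells overlap training data (e.g. {clash[0]}); "
                             "this would leak observed phenotypes into predictions")
    if X_new is None:
        X_new = np.ones((len(new_index), fit.X.shape[1]))
        if fit.X.shape[1] != 1:
            raise ValueError("X_new required for models with non-intercept fixed effects")
    result = pd.DataFrame(index=new_index.index)
    total = X_new @ fit.beta
    for t in fit.terms:
        if not isinstance(t, KronTerm):
            raise ValueError("prediction requires Kronecker terms for all effects")
        s2 = fit.varcomp[t.name]
        ia_new = t.A.indices(new_index["accession"])
        je_new = t.B.indices(new_index["environment"])
        ia_tr = t.A.indices(fit.index["accession"])
        je_tr = t.B.indices(fit.index["environment"])
        C = s2 * t.obs_matrix(ia_new, je_new, ia_tr, je_tr)
        comp = C @ fit.py
        result[t.name] = comp
        total = total + comp
    result["predicted"] = total
    return result


def lrt(fit0: ModelFit, fit1: ModelFit) -> LRTResult:
    """Likelihood-ratio test of nested REML fits.

    ``df`` is the difference in the number of variance components.  The raw
    LR is reported (it can be slightly negative when both optimizations stop
    at tolerance); it is clipped at zero for the chi-square p-value.  At the
    boundary of the parameter space the plain chi-square reference is
    conservative.
    """
    t0 = set(t.name for t in fit0.terms)
    t1 = set(t.name for t in fit1.terms)
    if not t0 < t1:
        raise ValueError(f"model {fit0.model or t0} is not nested in {fit1.model or t1}")
    df = len(t1) - len(t0)
    lr = -2.0 * (fit0.loglik - fit1.loglik)
    p = float(stats.chi2.sf(max(lr, 0.0), df))
    return LRTResult(lr=float(lr), df=df, pvalue=p)


def heritability(varcomp: dict) -> float:
    """Narrow-sense heritability from M3-style variance components.

    ``h2 = s2_A / (s2_A + s2_D + s2_AxEnv + s2_DxEnv + s2_residual)`` — the
    environmental main-effect variance is excluded from the denominator
    because accession means are z-scaled within each environment.
    """
    num = varcomp.get("A", 0.0)
    den = sum(varcomp.get(k, 0.0)
              for k in ("A", "D", "AxEnv", "DxEnv", "residual"))
    if den <= 0:
        raise ValueError("all variance components are zero: heritability undefined")
    return float(num / den)
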