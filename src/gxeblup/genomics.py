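"""From pooled allele depths to genomic kernels, LD curves, PCs and clusters.

Accessions here are outbreeding populations genotyped as pooled samples, so
the genotype signal per accession and marker is a pair of read depths
(reference, alternate) rather than a discrete dosage.  Allele frequencies are
estimated with pseudo-counts,

    p_ik = (AD_ALT + 1) / (AD_ALT + AD_REF + 2),

which shrinks low-depth cells toward 0.5 and forbids exact 0/1.  The additive
genomic relationship matrix is G_A = X X' / (tr(X X')/n) with X the
column-centered frequency matrix; the dominance matrix G_D is built the same
way from dominance codes — residuals of the per-marker regression of expected
heterozygosity H = 2 p q on p — which decorrelates the dominance and additive
model components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .kernels import DegenerateKernelError, Kernel, kernel_from_features

__all__ = [
    "AlleleDepths",
    "FrequencyMatrix",
    "FilterThresholds",
    "estimate_frequencies",
    "filter_markers",
    "impute_missing",
    "additive_kernel",
    "dominance_codes",
    "dominance_kernel",
    "ld_decay",
    "principal_components",
    "genetic_clusters",
]


@dataclass
class AlleleDepths:
    """Per-accession x per-marker reference/alternate read counts.

    ``ref`` and ``alt`` are (n_accessions, n_markers) integer arrays; missing
    genotypes are encoded explicitly by ``missing`` (0/0 depth cells become
    missing only through the depth filter, never silently).
    """

    ref: np.ndarray
    alt: np.ndarray
    accessions: list
    markers: pd.DataFrame  # columns: id, chrom, pos; optional qual
    missing: Optional[np.ndarray] = None

    def __post_init__(self):
        self.ref = np.asarray(self.ref)
        self.alt = np.asarray(self.alt)
        if self.ref.shape != self.alt.shape:
            raise ValueError("ref/alt depth matrices must have the same shape")
        if (self.ref < 0).any() or (self.alt < 0).any():
            raise ValueError("negative read depths")
        if self.missing is None:
            self.missing = np.zeros(self.ref.shape, dtype=bool)

    @property
    def depth(self) -> np.ndarray:
        return self.ref + self.alt


@dataclass
class FrequencyMatrix:
    """Pooled alternate-allele frequencies with an explicit missingness mask."""

    p: np.ndarray                  # (n_accessions, n_markers), NaN where missing
    accessions: list
    markers: pd.DataFrame

    @property
    def q(self) -> np.ndarray:
        return 1.0 - self.p

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.p)

    @property
    def n_accessions(self) -> int:
        return self.p.shape[0]

    @property
    def n_markers(self) -> int:
        return self.p.shape[1]

    def centered(self) -> np.ndarray:
        """X: per-marker mean removed (requires a complete matrix)."""
        if self.missing.any():
            raise ValueError("centering requires a complete (imputed) matrix")
        return self.p - self.p.mean(axis=0, keepdims=True)


@dataclass
class FilterThresholds:
    """Marker filters applied before kernel construction.

    Defaults: per-cell depth >= 10, per-marker mean depth in [20, 100],
    site quality >= 30 (skipped when no quality is available), pooled MAF
    >= 0.05, missing rate < 0.20.  ``mean_depth_max_is_lower_bound`` selects
    the literal alternative reading in which 100 bounds the mean depth from
    below rather than above.
    """

    min_dp: float = 10.0
    min_mean_dp: float = 20.0
    max_mean_dp: float = 100.0
    min_qual: float = 30.0
    min_maf: float = 0.05
    max_missing: float = 0.20
    mean_depth_max_is_lower_bound: bool = False


def estimate_frequencies(depths: AlleleDepths,
                         min_cell_depth: float = 10.0) -> FrequencyMatrix:
    """Pseudo-count allele frequencies; cells under the depth threshold are missing."""
    alt = depths.alt.astype(float)
    ref = depths.ref.astype(float)
    p = (alt + 1.0) / (alt + ref + 2.0)
    mask = depths.missing | (depths.depth < min_cell_depth)
    p = np.where(mask, np.nan, p)
    return FrequencyMatrix(p=p, accessions=list(depths.accessions),
                           markers=depths.markers.reset_index(drop=True))


def filter_markers(depths: AlleleDepths, freq: FrequencyMatrix,
                   thresholds: Optional[FilterThresholds] = None
                   ) -> tuple[FrequencyMatrix, pd.DataFrame]:
    """Remove markers failing depth, quality, MAF or missing-rate rules.

    Rules apply in order (mean depth, quality, MAF, missing rate); the report
    counts removals per rule at its point in the sequence.  MAF is the mean
    pooled frequency across accessions folded to the minor allele,
    min(p_bar, 1 - p_bar).
    """
    th = thresholds or FilterThresholds()
    n_markers = freq.n_markers
    keep = np.ones(n_markers, dtype=bool)
    report = []

    mean_dp = np.where(depths.missing, np.nan, depths.depth.astype(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_dp = np.nanmean(mean_dp, axis=0)
        mean_dp = np.nan_to_num(mean_dp, nan=0.0)
    if th.mean_depth_max_is_lower_bound:
        bad = (mean_dp < th.min_mean_dp) | (mean_dp < th.max_mean_dp)
    else:
        bad = (mean_dp < th.min_mean_dp) | (mean_dp > th.max_mean_dp)
    report.append(("mean_depth", int((bad & keep).sum())))
    keep &= ~bad

    if "qual" in freq.markers.columns:
        qual = freq.markers["qual"].to_numpy(dtype=float)
        bad = qual < th.min_qual
        report.append(("quality", int((bad & keep).sum())))
        keep &= ~bad
    else:
        report.append(("quality", 0))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pbar = np.nanmean(freq.p, axis=0)
    maf = np.fmin(pbar, 1.0 - pbar)
    bad = ~(maf >= th.min_maf)
    report.append(("maf", int((bad & keep).sum())))
    keep &= ~bad

    miss_rate = freq.missing.mean(axis=0)
    bad = miss_rate >= th.max_missing
    report.append(("missing_rate", int((bad & keep).sum())))
    keep &= ~bad

    if not keep.any():
        raise ValueError("all markers removed by filtering: empty panel")
    out = FrequencyMatrix(p=freq.p[:, keep], accessions=list(freq.accessions),
                          markers=freq.markers.loc[keep].reset_index(drop=True))
    rep = pd.DataFrame(report, columns=["rule", "n_removed"])
    rep.loc[len(rep)] = ("kept", int(keep.sum()))
    return out, rep


def impute_missing(freq: FrequencyMatrix) -> FrequencyMatrix:
    """Replace missing cells by the marker's mean over observed accessions."""
    p = freq.p.copy()
    miss = np.isnan(p)
    if miss.all(axis=0).any():
        bad = freq.markers.loc[miss.all(axis=0), "id"].tolist()
        raise ValueError(f"fully missing markers cannot be imputed: {bad[:5]}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_means = np.nanmean(p, axis=0)
    p[miss] = np.broadcast_to(col_means, p.shape)[miss]
    return FrequencyMatrix(p=p, accessions=list(freq.accessions),
                           markers=freq.markers.copy())


def additive_kernel(freq: FrequencyMatrix) -> Kernel:
    """G_A = X X' / (tr(X X')/n) from the centered frequency matrix."""
    X = freq.centered()
    return kernel_from_features(X, freq.accessions, center=False)


def dominance_codes(freq: FrequencyMatrix,
                    scope: str = "per-marker") -> np.ndarray:
    """Dominance codes: residuals of H = 2 p q regressed on allele frequency.

    Under HWE the expected heterozygosity of accession i at marker k is
    H_ik = 2 p_ik q_ik.  Ordinary least squares of H on (intercept, p) —
    per marker across accessions by default, or pooled over all cells with
    ``scope="global"`` — leaves residuals orthogonal to the additive
    regressor, decorrelating dominance from additive codes.
    """
    if freq.missing.any():
        raise ValueError("dominance codes require a complete (imputed) matrix")
    p = freq.p
    H = 2.0 * p * (1.0 - p)
    if scope == "global":
        x = p.ravel()
        h = H.ravel()
        A = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(A, h, rcond=None)
        return (h - A @ coef).reshape(p.shape)
    if scope != "per-marker":
        raise ValueError("scope must be 'per-marker' or 'global'")
    n = p.shape[0]
    pc = p - p.mean(axis=0, keepdims=True)
    hc = H - H.mean(axis=0, keepdims=True)
    sxx = (pc ** 2).sum(axis=0)
    sxy = (pc * hc).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
    if (sxx == 0).any():
        warnings.warn("markers with constant frequency yield all-zero dominance codes")
    return hc - pc * slope


def dominance_kernel(freq_or_codes, scope: str = "per-marker") -> Kernel:
    """G_D = D D' / (tr(D D')/n) from the dominance-code matrix."""
    if isinstance(freq_or_codes, FrequencyMatrix):
        codes = dominance_codes(freq_or_codes, scope=scope)
        labels = freq_or_codes.accessions
    else:
        codes = np.asarray(freq_or_codes, dtype=float)
        labels = [f"acc{i}" for i in range(codes.shape[0])]
    if not np.any(codes):
        raise DegenerateKernelError("all-zero dominance codes: kernel undefined")
    # codes are already mean-zero per marker; no further centering
    return kernel_from_features(codes, labels, center=False)


def ld_decay(freq: FrequencyMatrix, max_dist: int = 10_000,
             bins: Optional[np.ndarray] = None) -> dict:
    """Pairwise r^2 between same-chromosome markers vs physical distance.

    r^2 is the squared Pearson correlation of the two markers' alternate
    allele frequencies across accessions.  Pairs involving a zero-variance
    marker are skipped and counted.
    """
    if freq.missing.any():
        raise ValueError("LD computation requires a complete matrix")
    mk = freq.markers
    if not {"chrom", "pos"} <= set(mk.columns):
        raise ValueError("markers need 'chrom' and 'pos' columns for LD")
    X = freq.p
    sd = X.std(axis=0)
    sd[sd <= 1e-12 * np.maximum(1.0, np.abs(X).max(axis=0))] = 0.0
    rows = []
    n_skipped = 0
    for chrom, grp in mk.groupby("chrom", sort=False):
        order = grp.sort_values("pos")
        idx = order.index.to_numpy()
        pos = order["pos"].to_numpy()
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                d = pos[b] - pos[a]
                if d > max_dist:
                    break
                ka, kb = idx[a], idx[b]
                if sd[ka] == 0 or sd[kb] == 0:
                    n_skipped += 1
                    continue
                r = np.corrcoef(X[:, ka], X[:, kb])[0, 1]
                rows.append((chrom, d, r * r))
    pairs = pd.DataFrame(rows, columns=["chrom", "dist", "r2"])
    if bins is None:
        bins = np.linspace(0, max_dist, 21)
    if len(pairs):
        pairs["bin"] = pd.cut(pairs["dist"], bins, include_lowest=True)
        binned = (pairs.groupby("bin", observed=True)["r2"]
                  .agg(["mean", "count"]).reset_index())
        binned["dist_mid"] = binned["bin"].apply(lambda iv: iv.mid).astype(float)
    else:
        binned = pd.DataFrame(columns=["bin", "mean", "count", "dist_mid"])
    return {"pairs": pairs, "binned": binned, "n_skipped": n_skipped}


def principal_components(freq: FrequencyMatrix, k: int = 3
                         ) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the centered frequency matrix via SVD.

    Returns accession scores for the leading ``k`` components and the
    fractions of marker-space variance they explain.  Sign convention: the
    largest-magnitude loading of each component is positive.
    """
    X = freq.centered()
    r = np.linalg.matrix_rank(X)
    if k > min(X.shape) or k > r:
        raise ValueError(f"k={k} exceeds the rank ({r}) of the frequency matrix")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    for c in range(k):
        j = np.argmax(np.abs(Vt[c]))
        if Vt[c, j] < 0:
            Vt[c] *= -1.0
            U[:, c] *= -1.0
    scores = U[:, :k] * s[:k]
    varfrac = (s[:k] ** 2) / (s ** 2).sum()
    return (pd.DataFrame(scores, index=freq.accessions,
                         columns=[f"PC{i+1}" for i in range(k)]),
            varfrac)


def genetic_clusters(freq: FrequencyMatrix, k: int = 10) -> pd.Series:
    """Ward-linkage hierarchical clustering of accessions, cut to k clusters.

    Distances are Euclidean between accession rows of the centered frequency
    matrix; labels are 1..k.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if freq.n_accessions < k:
        raise ValueError("fewer accessions than requested clusters")
    X = freq.centered()
    Z = linkage(X, method="ward", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(labels)) != k:
        raise RuntimeError(f"Ward cut produced {len(np.unique(labels))} != {k} clusters")
    return pd.Series(labels, index=freq.accessions, name="cluster")
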