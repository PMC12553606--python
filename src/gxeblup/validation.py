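"""Cross-validation schemes and prediction-accuracy diagnostics.

Three schemes probe different prediction problems:

* leave-one-country-out — extrapolation to unobserved environments: both
  years of one country are held out; its environmental kernel rows remain
  valid because weather is observable without phenotypes;
* leave-one-random-cluster-out — prediction of unobserved accessions with
  relatives in training: accessions are randomly split into ten clusters;
* leave-one-genetic-cluster-out — prediction across genetic distance: the
  held-out cluster comes from Ward clustering of the genotype matrix, so
  training relatives are scarce.

Prediction accuracy per fold is the Pearson correlation between observed and
predicted accession means over the fold's test cells (pooled across
environments); scheme-level accuracy is the mean over folds, not the pooled
correlation.  Component-wise correlations (between observed test means and
each predicted model component) show which effects carry the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .reml import ModelFit, predict_cells, reml_fit

__all__ = [
    "FoldSpec",
    "CVResult",
    "make_country_folds",
    "make_random_folds",
    "make_genetic_folds",
    "run_cv",
    "component_correlations",
]


@dataclass
class FoldSpec:
    """One train/test split of the stage-2 observations."""

    scheme: str
    fold_id: str
    test_mask: np.ndarray = field(repr=False)
    held_out: object = None

    def train_mask(self) -> np.ndarray:
        return ~self.test_mask


def _check_partition(folds: list, n: int) -> None:
    total = np.zeros(n, dtype=int)
    for f in folds:
        total += f.test_mask.astype(int)
    if not np.all(total == 1):
        raise RuntimeError("folds do not partition the observations")


def make_country_folds(index: pd.DataFrame) -> list:
    """One fold per country with observations; both its years are held out."""
    if "country" not in index.columns:
        raise ValueError("index needs a 'country' column")
    countries = list(pd.unique(index["country"]))
    if len(countries) < 2:
        raise ValueError("leave-one-country-out needs >= 2 scored countries")
    folds = [FoldSpec("country", c, (index["country"] == c).to_numpy(), c)
             for c in countries]
    _check_partition(folds, len(index))
    return folds


def make_random_folds(index: pd.DataFrame, k: int = 10, seed: int = 0) -> list:
    """Seeded near-equal random partition of accessions into k clusters."""
    if k < 2:
        raise ValueError("k must be >= 2")
    accs = np.array(sorted(pd.unique(index["accession"])))
    if len(accs) < k:
        raise ValueError("fewer accessions than folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(accs))
    assign = np.empty(len(accs), dtype=int)
    assign[perm] = np.arange(len(accs)) % k
    lookup = dict(zip(accs, assign))
    labels = index["accession"].map(lookup).to_numpy()
    folds = [FoldSpec("random-cluster", f"cluster{c + 1}", labels == c,
                      set(accs[assign == c])) for c in range(k)]
    _check_partition(folds, len(index))
    return folds


def make_genetic_folds(index: pd.DataFrame, clusters: pd.Series) -> list:
    """One fold per genetic cluster (Ward clustering of the genotype panel)."""
    accs = pd.unique(index["accession"])
    missing = [a for a in accs if a not in clusters.index]
    if missing:
        raise ValueError(f"accessions without cluster assignment: {missing[:5]}")
    labels = index["accession"].map(clusters).to_numpy()
    folds = []
    for c in sorted(pd.unique(clusters.loc[accs])):
        mask = labels == c
        if not mask.any():
            raise ValueError(f"cluster {c} holds no observations")
        held = set(clusters.index[clusters == c]) & set(accs)
        folds.append(FoldSpec("genetic-cluster", f"cluster{c}", mask, held))
    _check_partition(folds, len(index))
    return folds


@dataclass
class CVResult:
    """Per-fold prediction accuracies and scheme-level summary."""

    scheme: str
    model: str
    per_fold: pd.DataFrame            # fold, n_test, r
    per_environment: pd.DataFrame     # fold x environment breakdown
    fits: list = field(repr=False, default_factory=list)
    predictions: list = field(repr=False, default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(self.per_fold["r"].mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.per_fold["r"].std(ddof=1))


def _leakage_check(fold: FoldSpec, index: pd.DataFrame) -> None:
    tr = index.loc[fold.train_mask()]
    te = index.loc[fold.test_mask]
    if fold.scheme in ("random-cluster", "genetic-cluster"):
        overlap = set(tr["accession"]) & set(te["accession"])
        if overlap:
            raise RuntimeError(f"held-out accessions appear in training: "
                               f"{sorted(overlap)[:5]}")
    if fold.scheme == "country" and "country" in index.columns:
        if fold.held_out in set(tr["country"]):
            raise RuntimeError(f"held-out country {fold.held_out} in training")


def run_cv(
    y,
    index: pd.DataFrame,
    terms: Sequence,
    folds: Sequence[FoldSpec],
    model: str = "",
    warm_start: Optional[np.ndarray] = None,
    min_test: int = 3,
) -> CVResult:
    """Refit by REML per fold, predict held-out cells, score Pearson accuracy.

    ``warm_start`` (variance components from a full-data fit) cuts the cost
    of per-fold refits; folds with fewer than ``min_test`` test cells are
    excluded from the summary with a notice column.
    """
    y = np.asarray(y, dtype=float)
    rows, env_rows, fits, preds = [], [], [], []
    for fold in folds:
        _leakage_check(fold, index)
        tr, te = fold.train_mask(), fold.test_mask
        fit = reml_fit(y[tr], index.loc[tr], terms, model=model,
                       init=warm_start)
        pred = predict_cells(fit, index.loc[te])
        obs = pd.Series(y[te], index=pred.index)
        n_test = int(te.sum())
        r = np.nan
        if n_test >= min_test and obs.std() > 0 and pred["predicted"].std() > 0:
            r = float(np.corrcoef(obs, pred["predicted"])[0, 1])
        rows.append((fold.fold_id, n_test, r))
        sub = index.loc[te]
        for env, grp in pred.groupby(sub["environment"]):
            o = obs.loc[grp.index]
            if len(grp) >= min_test and o.std() > 0 and grp["predicted"].std() > 0:
                env_rows.append((fold.fold_id, env,
                                 float(np.corrcoef(o, grp["predicted"])[0, 1]),
                                 len(grp)))
        fits.append(fit)
        preds.append((fold, pred, obs))
    per_fold = pd.DataFrame(rows, columns=["fold", "n_test", "r"])
    per_env = pd.DataFrame(env_rows, columns=["fold", "environment", "r", "n"])
    return CVResult(scheme=folds[0].scheme if folds else "", model=model,
                    per_fold=per_fold, per_environment=per_env,
                    fits=fits, predictions=preds)


def component_correlations(cv: CVResult) -> pd.DataFrame:
    """Correlation between observed test means and each predicted component.

    Per fold and component, the Pearson correlation between the observed
    held-out accession means and that component's contribution to the
    prediction; constant component predictions (e.g. a variance estimated at
    zero) yield a missing entry rather than a fabricated value.  The "total"
    row reproduces the fold's prediction accuracy.
    """
    rows = []
    for fold, pred, obs in cv.predictions:
        comps = [c for c in pred.columns if c != "predicted"] + ["predicted"]
        for comp in comps:
            v = pred[comp]
            label = "total" if comp == "predicted" else comp
            if v.std() == 0 or obs.std() == 0 or len(v) < 3:
                rows.append((fold.fold_id, label, np.nan))
            else:
                rows.append((fold.fold_id, label,
                             float(np.corrcoef(obs, v)[0, 1])))
    long = pd.DataFrame(rows, columns=["fold", "component", "r"])
    summary = (long.groupby("component")["r"]
               .agg(mean="mean", sd=lambda s: s.std(ddof=1), n_folds="count")
               .reset_index())
    return summary.merge(long.pivot(index="component", columns="fold",
                                    values="r").reset_index(),
                         on="component")
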