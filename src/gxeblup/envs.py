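"""Environmental covariates: windows, thermal time, RN/ET features, E kernels.

Two ways of measuring environment relatedness from daily weather:

* reaction norm (RN): the mean of each covariate within each 30-day window,
  per environment (country-year);
* envirotyping (ET): within each covariate x window, daily values are binned
  by quantile cut-points (0.05, 0.25, 0.50, 0.95) computed on the values
  pooled across environments, and the feature is the within-environment
  frequency of each of the five bins.

Windows tile the trait's extraction range: 1 September of the year before
harvest to 31 August of the harvest year for seasonal yield, or to 31 May for
the persistence traits scored in spring.  The environment kernel E is built
from the feature table exactly like a genomic relationship matrix,
W W' / (tr(W W')/n); feature columns are standardized by default because RN
covariates carry incommensurate units.

Thermal covariates use the cardinal temperatures of the crop (base 3.2 °C,
optimum plateau 10-30 °C, upper limit 52 °C) in a piecewise-linear trapezoid
response scaled to [0, 1] per day.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .kernels import Kernel, kernel_from_features

__all__ = [
    "CardinalTemps",
    "WindowSpec",
    "build_windows",
    "thermal_response",
    "derive_thermal_covariates",
    "rn_features",
    "et_features",
    "env_kernel",
    "DEFAULT_COVARIATES",
]

#: Daily covariates the weather generator produces and the feature builders
#: consume by default.  This is a typical agro-climatic set (temperatures,
#: moisture, radiation, wind plus derived thermal indices), not a canonical
#: list; any named set can be supplied instead.
DEFAULT_COVARIATES = [
    "tmin", "tmean", "tmax", "precipitation", "humidity", "radiation", "wind",
]


@dataclass
class CardinalTemps:
    """Cardinal temperatures (°C) bounding crop development."""

    base: float = 3.2
    opt_low: float = 10.0
    opt_high: float = 30.0
    upper: float = 52.0

    def __post_init__(self):
        if not (self.base < self.opt_low < self.opt_high < self.upper):
            raise ValueError("cardinal temperatures must be strictly increasing")


@dataclass
class WindowSpec:
    """Consecutive windows tiling a trait's covariate-extraction range."""

    trait: str
    start: dt.date
    end: dt.date
    length: int = 30
    windows: list = field(default_factory=list)  # list of (start, end) inclusive

    @property
    def n_windows(self) -> int:
        return len(self.windows)


TRAIT_RANGES = {
    # trait -> (start month/day in year-1, end month/day in harvest year)
    "TDM3": ((9, 1), (8, 31)),
    "SpringCover": ((9, 1), (5, 31)),
    "WinterKill": ((9, 1), (5, 31)),
}


def build_windows(trait: str, harvest_year: int, length: int = 30,
                  custom_range: Optional[tuple] = None,
                  keep_remainder: bool = True) -> WindowSpec:
    """Partition a trait's extraction range into consecutive windows.

    Seasonal yield runs 1 Sep (year-1) to 31 Aug; persistence traits stop at
    31 May.  The final short window (365 is not a multiple of 30) is kept as
    its own window unless ``keep_remainder`` is False.
    """
    if custom_range is not None:
        start, end = custom_range
    elif trait in TRAIT_RANGES:
        (sm, sd), (em, ed) = TRAIT_RANGES[trait]
        start = dt.date(harvest_year - 1, sm, sd)
        end = dt.date(harvest_year, em, ed)
    else:
        raise ValueError(f"unknown trait {trait!r} and no custom range supplied")
    if end <= start:
        raise ValueError("window range end must follow start")
    windows = []
    cur = start
    while cur <= end:
        wend = min(cur + dt.timedelta(days=length - 1), end)
        if wend < cur + dt.timedelta(days=length - 1) and not keep_remainder:
            break
        windows.append((cur, wend))
        cur = wend + dt.timedelta(days=1)
    return WindowSpec(trait=trait, start=start, end=end, length=length,
                      windows=windows)


def thermal_response(t: np.ndarray, cardinal: Optional[CardinalTemps] = None
                     ) -> np.ndarray:
    """Trapezoid development response in [0, 1] for daily mean temperature."""
    c = cardinal or CardinalTemps()
    t = np.asarray(t, dtype=float)
    r = np.zeros_like(t)
    rise = (t > c.base) & (t < c.opt_low)
    r[rise] = (t[rise] - c.base) / (c.opt_low - c.base)
    r[(t >= c.opt_low) & (t <= c.opt_high)] = 1.0
    fall = (t > c.opt_high) & (t < c.upper)
    r[fall] = (c.upper - t[fall]) / (c.upper - c.opt_high)
    return r


def derive_thermal_covariates(weather: pd.DataFrame,
                              cardinal: Optional[CardinalTemps] = None,
                              temp_covariate: str = "tmean") -> pd.DataFrame:
    """Add thermal-time and cold-stress covariates to a long weather table.

    ``thermal_time``: trapezoid response x 1 day (degree-day equivalent on a
    0-1 scale); ``cold_stress``: indicator of days below the base temperature.
    """
    c = cardinal or CardinalTemps()
    t = weather[weather["covariate"] == temp_covariate]
    if t.empty:
        raise ValueError(f"no {temp_covariate!r} covariate in weather table")
    tt = t.copy()
    tt["covariate"] = "thermal_time"
    tt["value"] = thermal_response(t["value"].to_numpy(), c)
    cs = t.copy()
    cs["covariate"] = "cold_stress"
    cs["value"] = (t["value"].to_numpy() < c.base).astype(float)
    return pd.concat([weather, tt, cs], ignore_index=True)


def _env_label(site, year) -> str:
    return f"{site}-{year}"


def _windowed(weather: pd.DataFrame, windows: WindowSpec, harvest_years: dict,
              covariates: Sequence[str]) -> pd.DataFrame:
    """Assign each daily record to (environment, window index); drop the rest.

    ``harvest_years`` maps site -> list of harvest years; the window calendar
    is anchored per harvest year.
    """
    w = weather[weather["covariate"].isin(covariates)].copy()
    w["date"] = pd.to_datetime(w["date"]).dt.date
    frames = []
    for site, years in harvest_years.items():
        ws = w[w["site"] == site]
        for year in years:
            spec = build_windows(windows.trait, year, windows.length)
            lo, hi = spec.start, spec.end
            sel = ws[(ws["date"] >= lo) & (ws["date"] <= hi)].copy()
            have = set(sel["date"])
            span = (hi - lo).days + 1
            if len(have) < span:
                raise ValueError(
                    f"weather for site {site!r} does not cover "
                    f"{lo}..{hi} ({len(have)}/{span} days present)")
            offs = sel["date"].apply(lambda d: (d - lo).days)
            sel["window"] = np.minimum(offs // windows.length,
                                       spec.n_windows - 1)
            sel["environment"] = _env_label(site, year)
            frames.append(sel)
    if not frames:
        raise ValueError("no weather rows matched the requested sites/years")
    return pd.concat(frames, ignore_index=True)


def rn_features(weather: pd.DataFrame, windows: WindowSpec,
                harvest_years: dict,
                covariates: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Reaction-norm features: environment means per covariate x window."""
    covariates = list(covariates or DEFAULT_COVARIATES)
    long = _windowed(weather, windows, harvest_years, covariates)
    feats = (long.groupby(["environment", "covariate", "window"])["value"]
             .mean().reset_index())
    feats["feature"] = (feats["covariate"] + "_w"
                        + feats["window"].astype(str).str.zfill(2))
    table = feats.pivot(index="environment", columns="feature", values="value")
    if table.isna().any().any():
        missing = table.columns[table.isna().any()].tolist()
        raise ValueError(f"windows without data: {missing[:5]}")
    return table.sort_index()


def et_features(weather: pd.DataFrame, windows: WindowSpec,
                harvest_years: dict,
                covariates: Optional[Sequence[str]] = None,
                quantiles: Sequence[float] = (0.05, 0.25, 0.50, 0.95),
                pool_environments: bool = True) -> pd.DataFrame:
    """Envirotype features: per-bin daily-value frequencies per covariate x window.

    Cut-points are the given quantiles of the daily values pooled across all
    environments for that covariate x window (making bin frequencies
    comparable between environments); ``pool_environments=False`` computes
    them within each environment instead.  The five bin frequencies for one
    covariate x window sum to one per environment.
    """
    covariates = list(covariates or DEFAULT_COVARIATES)
    qs = sorted(quantiles)
    long = _windowed(weather, windows, harvest_years, covariates)
    envs = sorted(long["environment"].unique())
    rows = {}
    for (cov, win), grp in long.groupby(["covariate", "window"]):
        if pool_environments:
            cuts = np.quantile(grp["value"], qs)
        for env in envs:
            vals = grp.loc[grp["environment"] == env, "value"].to_numpy()
            if not pool_environments:
                cuts = np.quantile(vals, qs)
            binned = np.searchsorted(cuts, vals, side="left")
            freq = np.bincount(binned, minlength=len(qs) + 1) / len(vals)
            for b, f in enumerate(freq):
                rows.setdefault(env, {})[f"{cov}_w{win:02d}_bin{b}"] = f
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "environment"
    return table[sorted(table.columns)]


def env_kernel(features: pd.DataFrame, scale: bool = True) -> Kernel:
    """E = W W' / (tr(W W')/n_env) from an environment feature table.

    Columns are centered; with ``scale`` (default) they are also divided by
    their standard deviation so covariates with large units do not dominate.
    """
    if features.shape[0] < 2:
        raise ValueError("environment kernel needs at least two environments")
    if features.isna().any().any():
        raise ValueError("feature table contains missing values")
    return kernel_from_features(features.to_numpy(dtype=float),
                                list(features.index), center=True, scale=scale)
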