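"""Synthetic genotypes, weather, trial designs and phenotypes.

The generator emulates the statistical structure of a Nordic-Baltic
multi-environment ryegrass trial: 264 outbreeding accessions genotyped as
pooled samples with weak subpopulation structure and rapid LD decay; six
countries x two years = twelve environments; unbalanced scoring with a
108-accession core evaluated everywhere; phenotypes drawn from the M3
covariance structure (additive, environmental, additive x environment,
dominance, dominance x environment, residual); plot-level expansion with
year, trial/replicate and AR1 row/column field effects; and optional
embedded QTL with a marginal effect plus country-specific deviations.

Accessions are populations, not inbred lines, so the per-accession genotype
at a marker is a continuous pool allele frequency (Balding-Nichols
subpopulation frequencies perturbed by Beta-distributed within-accession
drift), observed through binomially sampled sequencing reads.  Markers are
simulated independently by default — downstream methods treat markers
exchangeably — with a separate correlated-block mode for LD-decay testing.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genomics import AlleleDepths, FrequencyMatrix
from .kernels import Kernel

__all__ = [
    "CountrySpec",
    "DesignSpec",
    "QTL",
    "SpatialParams",
    "TruthRecord",
    "default_design",
    "complete_design",
    "simulate_population",
    "simulate_weather",
    "simulate_phenotypes",
    "simulate_stage2",
]


# ---------------------------------------------------------------------------
# trial design
# ---------------------------------------------------------------------------

@dataclass
class CountrySpec:
    """One trial site: accession count, layout and climate parameters."""

    name: str
    n_accessions: int
    latitude: float = 58.0
    n_trials: int = 2          # iid trial/replicate blocks per environment
    rows: int = 0              # field rows per trial (0 = square-ish auto)
    cols: int = 0

    def layout(self) -> tuple[int, int]:
        if self.rows and self.cols:
            if self.rows * self.cols < self.n_accessions:
                raise ValueError(
                    f"{self.name}: {self.rows}x{self.cols} grid too small for "
                    f"{self.n_accessions} accessions")
            return self.rows, self.cols
        r = int(np.ceil(np.sqrt(self.n_accessions)))
        c = int(np.ceil(self.n_accessions / r))
        return r, c


@dataclass
class DesignSpec:
    """Which accessions are scored where: the unbalanced trial design.

    ``traits`` maps trait name to the list of scored (country, year) cells.
    ``country_accessions`` (derived) nests a core of ``core_size`` accessions
    inside every country's set, with non-core accessions distributed to fill
    the per-country counts.
    """

    countries: list
    years: list
    traits: dict
    core_size: int = 108
    n_total: int = 264
    country_accessions: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        names = {c.name for c in self.countries}
        for trait, cells in self.traits.items():
            for country, year in cells:
                if country not in names:
                    raise ValueError(f"{trait}: unknown country {country!r}")
                if year not in self.years:
                    raise ValueError(f"{trait}: unknown year {year!r}")
        if any(c.n_accessions < self.core_size for c in self.countries):
            raise ValueError("every country must hold at least the core set")
        if not self.country_accessions:
            self.country_accessions = self._assign_accessions()
        for c in self.countries:
            got = self.country_accessions[c.name]
            if len(got) != c.n_accessions:
                raise ValueError(f"{c.name}: accession assignment mismatch")
            if not set(self.accessions[: self.core_size]) <= set(got):
                raise ValueError(f"{c.name}: core accessions missing")

    @property
    def accessions(self) -> list:
        width = len(str(self.n_total))
        return [f"acc{str(i + 1).zfill(width)}" for i in range(self.n_total)]

    @property
    def core_accessions(self) -> list:
        return self.accessions[: self.core_size]

    @property
    def environments(self) -> list:
        return [f"{c.name}-{y}" for c in self.countries for y in self.years]

    def _assign_accessions(self) -> dict:
        """Nest the core everywhere; cycle non-core ids so all are used."""
        acc = self.accessions
        core = acc[: self.core_size]
        noncore = acc[self.core_size:]
        need = sum(c.n_accessions - self.core_size for c in self.countries)
        if need < len(noncore):
            raise ValueError("per-country counts cannot cover all non-core accessions")
        out = {}
        offset = 0
        for c in sorted(self.countries, key=lambda c: -c.n_accessions):
            extra = c.n_accessions - self.core_size
            take = [noncore[(offset + i) % len(noncore)] for i in range(extra)]
            offset += extra
            out[c.name] = core + sorted(set(take))
            if len(out[c.name]) != c.n_accessions:
                # wrapped past the pool: pad with unused ids deterministically
                pool = [a for a in noncore if a not in out[c.name]]
                out[c.name] = core + sorted(set(take) | set(pool[: extra - len(set(take))]))
        return out

    def scored_environments(self, trait: str) -> list:
        return [f"{c}-{y}" for c, y in self.traits[trait]]


def default_design() -> DesignSpec:
    """The study design: 6 countries x 2 years, nested unbalanced scoring.

    Accessions per country: Norway 213, Estonia 144, Sweden 108, Lithuania
    118, Iceland 142, Denmark 262; 264 in total with a 108-accession core
    common to all sites.  Seasonal yield (TDM3) is scored everywhere except
    Iceland; spring cover in Norway, Estonia, Lithuania and Iceland; winter
    kill only in the three 2016 environments that experienced winter stress.
    """
    countries = [
        CountrySpec("Norway", 213, latitude=60.75),
        CountrySpec("Estonia", 144, latitude=58.75),
        CountrySpec("Sweden", 108, latitude=55.93),
        CountrySpec("Lithuania", 118, latitude=55.38),
        CountrySpec("Iceland", 142, latitude=64.15),
        CountrySpec("Denmark", 262, latitude=55.33),
    ]
    years = [2015, 2016]
    both = lambda names: [(c, y) for c in names for y in years]
    traits = {
        "TDM3": both(["Norway", "Estonia", "Sweden", "Lithuania", "Denmark"]),
        "SpringCover": both(["Norway", "Estonia", "Lithuania", "Iceland"]),
        "WinterKill": [("Estonia", 2016), ("Sweden", 2016), ("Lithuania", 2016)],
    }
    return DesignSpec(countries=countries, years=years, traits=traits,
                      core_size=108, n_total=264)


def complete_design(n_accessions: int, countries: Optional[Sequence] = None,
                    years: Sequence = (2015, 2016), trait: str = "TDM3",
                    core_size: Optional[int] = None) -> DesignSpec:
    """A balanced design: every accession scored in every country-year cell."""
    if countries is None:
        countries = [c.name for c in default_design().countries]
    specs = []
    for c in countries:
        if isinstance(c, CountrySpec):
            specs.append(CountrySpec(c.name, n_accessions, c.latitude))
        else:
            lat = {cc.name: cc.latitude for cc in default_design().countries
                   }.get(c, 58.0)
            specs.append(CountrySpec(c, n_accessions, lat))
    traits = {trait: [(c.name, y) for c in specs for y in years]}
    return DesignSpec(countries=specs, years=list(years), traits=traits,
                      core_size=core_size or n_accessions,
                      n_total=n_accessions)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_population(
    n_accessions: int = 264,
    n_markers: int = 1000,
    n_subpops: int = 10,
    divergence: float = 0.02,
    depth_mean: float = 40.0,
    seed: int = 0,
    maf_range: tuple = (0.10, 0.90),
    within_acc_concentration: float = 30.0,
    n_chromosomes: int = 7,
    chrom_length: int = 1_000_000,
    ld_decay_length: Optional[float] = None,
    accession_labels: Optional[Sequence[str]] = None,
) -> tuple[AlleleDepths, FrequencyMatrix, np.ndarray]:
    """Simulate pooled-GBS allele depths for a structured panel.

    Ancestral frequencies are uniform on ``maf_range``; subpopulation
    frequencies follow a Balding-Nichols perturbation with F = ``divergence``
    (F = 0 leaves labels uninformative); per-accession pool frequencies are
    Beta-distributed around the subpopulation frequency; read depths are
    Poisson around ``depth_mean`` and alternate counts binomial.  With
    ``ld_decay_length`` set, latent accession deviations follow an AR process
    over marker order so inter-marker correlation decays as
    exp(-distance/length).

    Returns (depths, true pool-frequency matrix, subpopulation labels).
    """
    if n_accessions < 2 or n_markers < 1:
        raise ValueError("need at least 2 accessions and 1 marker")
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    if not (0.0 <= divergence < 1.0):
        raise ValueError("divergence must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if accession_labels is None:
        width = len(str(n_accessions))
        accession_labels = [f"acc{str(i + 1).zfill(width)}"
                            for i in range(n_accessions)]

    chrom = rng.integers(1, n_chromosomes + 1, size=n_markers)
    pos = rng.integers(1, chrom_length + 1, size=n_markers)
    order = np.lexsort((pos, chrom))
    chrom, pos = chrom[order], pos[order]
    markers = pd.DataFrame({
        "id": [f"chr{c}_{p}" for c, p in zip(chrom, pos)],
        "chrom": chrom, "pos": pos,
    })

    p_anc = rng.uniform(*maf_range, size=n_markers)
    subpop = rng.integers(0, n_subpops, size=n_accessions)
    if divergence > 0:
        c = (1.0 - divergence) / divergence
        sub_freq = rng.beta(np.maximum(p_anc * c, 1e-3),
                            np.maximum((1.0 - p_anc) * c, 1e-3),
                            size=(n_subpops, n_markers))
    else:
        sub_freq = np.broadcast_to(p_anc, (n_subpops, n_markers)).copy()

    base = sub_freq[subpop]  # (n_acc, n_markers)
    if ld_decay_length is None:
        kappa = within_acc_concentration
        pool = rng.beta(np.maximum(base * kappa, 1e-3),
                        np.maximum((1.0 - base) * kappa, 1e-3))
    else:
        # correlated deviations: AR over marker order within chromosome
        z = np.empty((n_accessions, n_markers))
        prev_chrom = None
        for k in range(n_markers):
            eps = rng.standard_normal(n_accessions)
            if chrom[k] != prev_chrom:
                z[:, k] = eps
            else:
                rho = float(np.exp(-(pos[k] - pos[k - 1]) / ld_decay_length))
                z[:, k] = rho * z[:, k - 1] + np.sqrt(1.0 - rho ** 2) * eps
            prev_chrom = chrom[k]
        sd = np.sqrt(base * (1.0 - base) / (within_acc_concentration + 1.0))
        pool = base + sd * z
    pool = np.clip(pool, 0.01, 0.99)

    depth = rng.poisson(depth_mean, size=pool.shape)
    alt = rng.binomial(depth, pool)
    ref = depth - alt
    depths = AlleleDepths(ref=ref, alt=alt, accessions=list(accession_labels),
                          markers=markers)
    truth = FrequencyMatrix(p=pool, accessions=list(accession_labels),
                            markers=markers.copy())
    return depths, truth, subpop


# ---------------------------------------------------------------------------
# weather
# ---------------------------------------------------------------------------

#: covariate -> (does it derive from the temperature process, offset, scale)
_WEATHER_BASE = {
    "tmean": None,
    "tmin": None,
    "tmax": None,
    "precipitation": (1.5, 2.0),
    "humidity": (75.0, 8.0),
    "radiation": (12.0, 6.0),
    "wind": (4.0, 1.5),
}


def simulate_weather(
    design: DesignSpec,
    covariates: Optional[Sequence[str]] = None,
    seed: int = 0,
    noise_sd: float = 1.5,
    phi: float = 0.7,
) -> pd.DataFrame:
    """Daily weather per site: seasonal sinusoid + site offset + AR(1) noise.

    Covers 1 Sep (first year - 1) through 31 Aug (last year) for every site.
    Temperature covariates satisfy tmin <= tmean <= tmax by construction;
    with ``noise_sd = 0`` every series is the deterministic seasonal curve.
    Annual mean and amplitude are crude functions of site latitude — enough
    to make sites distinct and seasons realistic in shape, with no claim to
    meteorological fidelity.
    """
    covariates = list(covariates or
                      ["tmin", "tmean", "tmax", "precipitation",
                       "humidity", "radiation", "wind"])
    unknown = [c for c in covariates if c not in _WEATHER_BASE]
    if unknown:
        raise ValueError(f"unknown covariates {unknown}; "
                         f"available: {sorted(_WEATHER_BASE)}")
    if not covariates:
        raise ValueError("covariate list is empty")
    rng = np.random.default_rng(seed)
    start = dt.date(min(design.years) - 1, 9, 1)
    end = dt.date(max(design.years), 8, 31)
    dates = pd.date_range(start, end, freq="D")
    doy = dates.day_of_year.to_numpy()
    season = -np.cos(2.0 * np.pi * (doy - 15) / 365.25)  # peak mid-July

    def ar1(n, sd):
        if sd == 0.0:
            return np.zeros(n)
        e = rng.standard_normal(n) * sd * np.sqrt(1.0 - phi ** 2)
        x = np.empty(n)
        x[0] = rng.standard_normal() * sd
        for t in range(1, n):
            x[t] = phi * x[t - 1] + e[t]
        return x

    frames = []
    for c in design.countries:
        level = 22.0 - 0.30 * c.latitude
        amp = 8.0 + 0.15 * (c.latitude - 50.0)
        tmean = level + amp * season + ar1(len(dates), noise_sd)
        series = {"tmean": tmean,
                  "tmin": tmean - 4.0 + ar1(len(dates), 0.5 * noise_sd).clip(max=3.9),
                  "tmax": tmean + 4.0 + ar1(len(dates), 0.5 * noise_sd).clip(min=-3.9)}
        for cov in covariates:
            if cov in series:
                vals = series[cov]
            else:
                off, sc = _WEATHER_BASE[cov]
                base = off + sc * 0.3 * season
                vals = np.maximum(base + sc * 0.3 * ar1(len(dates), noise_sd), 0.0)
            frames.append(pd.DataFrame({
                "site": c.name, "date": dates, "covariate": cov, "value": vals,
            }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

@dataclass
class QTL:
    """An embedded causal marker: marginal effect plus country deviations."""

    marker: str
    alpha: float
    delta: dict = field(default_factory=dict)  # country -> deviation


@dataclass
class SpatialParams:
    """Plot-level design effects added on top of accession-environment means."""

    var_year: float = 0.05
    var_trial: float = 0.05
    var_row: float = 0.05
    var_col: float = 0.05
    var_plot: float = 0.10
    rho_row: float = 0.4
    rho_col: float = 0.4

    def validate(self):
        for f, v in asdict(self).items():
            if f.startswith("var_") and v < 0:
                raise ValueError(f"{f} must be non-negative")
        if not (abs(self.rho_row) < 1 and abs(self.rho_col) < 1):
            raise ValueError("AR1 correlations must lie in (-1, 1)")


@dataclass
class TruthRecord:
    """Everything needed to recompose and verify a simulated trait."""

    seed: int
    mu: float
    varcomp: dict
    a: pd.Series
    d: pd.Series
    e: pd.Series
    ae: pd.DataFrame
    de: pd.DataFrame
    qtl: list
    cell_means: pd.DataFrame  # accession x environment, NaN where unscored
    spatial: SpatialParams

    def recompose(self, accession: str, environment: str) -> float:
        country = environment.rsplit("-", 1)[0]
        val = self.mu + self.a[accession] + self.d[accession] + self.e[environment]
        val += self.ae.loc[accession, environment] + self.de.loc[accession, environment]
        for q in self.qtl:
            val += q["s"][accession] * (q["alpha"] + q["delta"].get(country, 0.0))
        return val

    def to_json(self, path):
        payload = {
            "seed": self.seed, "mu": self.mu, "varcomp": self.varcomp,
            "a": self.a.to_dict(), "d": self.d.to_dict(), "e": self.e.to_dict(),
            "ae": self.ae.to_dict(), "de": self.de.to_dict(),
            "qtl": [{"marker": q["marker"], "alpha": q["alpha"],
                     "delta": q["delta"]} for q in self.qtl],
            "spatial": asdict(self.spatial),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _ar1_chol(rho: float, m: int) -> np.ndarray:
    idx = np.arange(m)
    C = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(C + 1e-12 * np.eye(m))


def _mvn(rng, kernel: Kernel, var: float, size=None) -> np.ndarray:
    if var == 0.0:
        n = kernel.n
        return np.zeros(n if size is None else (n, size))
    w, V = np.linalg.eigh((kernel.values + kernel.values.T) / 2.0)
    L = V * np.sqrt(np.maximum(w, 0.0))
    if size is None:
        return np.sqrt(var) * (L @ rng.standard_normal(kernel.n))
    return np.sqrt(var) * (L @ rng.standard_normal((kernel.n, size)))


def simulate_phenotypes(
    design: DesignSpec,
    trait: str,
    G_A: Kernel,
    E: Kernel,
    G_D: Optional[Kernel] = None,
    varcomp: Optional[dict] = None,
    qtl: Optional[Sequence[QTL]] = None,
    freq: Optional[FrequencyMatrix] = None,
    spatial: Optional[SpatialParams] = None,
    mu: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Draw phenotypes under the M3 covariance structure and expand to plots.

    Component draws: a ~ N(0, s2_A G_A), d ~ N(0, s2_D G_D), e ~ N(0, s2_E E),
    ae ~ N(0, s2_AxE G_A (x) E), de ~ N(0, s2_DxE G_D (x) E).  Cell means are
    mu + a_i + e_j + ae_ij + d_i + de_ij plus QTL terms s_i (alpha + delta_c);
    plot records add year, trial and AR1 row/column effects plus iid noise.

    ``varcomp`` keys: A, Env, AxEnv, D, DxEnv, residual (the residual acts at
    the accession-mean level; plot noise is governed by ``spatial.var_plot``).
    """
    vc = {"A": 0.35, "Env": 0.02, "AxEnv": 0.18, "D": 0.15, "DxEnv": 0.17,
          "residual": 0.15}
    if varcomp is not None:
        unknown = set(varcomp) - set(vc)
        if unknown:
            raise ValueError(f"unknown variance components {sorted(unknown)}")
        vc.update(varcomp)
    if any(v < 0 for v in vc.values()):
        raise ValueError("variance components must be non-negative")
    if (vc["D"] > 0 or vc["DxEnv"] > 0) and G_D is None:
        raise ValueError("dominance variance requested without a dominance kernel")
    spatial = spatial or SpatialParams()
    spatial.validate()
    if trait not in design.traits:
        raise ValueError(f"trait {trait!r} not in design")
    rng = np.random.default_rng(seed)

    accs = design.accessions
    envs = design.environments
    GA = G_A.subset(accs)
    Ek = E.subset(envs)
    GD = G_D.subset(accs) if G_D is not None else None

    a = _mvn(rng, GA, vc["A"])
    e = _mvn(rng, Ek, vc["Env"])
    # matrix-normal draw: chol(G) Z chol(E)' has covariance G (x) E
    wA, VA = np.linalg.eigh(GA.values)
    LA = VA * np.sqrt(np.maximum(wA, 0.0))
    wE, VE = np.linalg.eigh(Ek.values)
    LE = VE * np.sqrt(np.maximum(wE, 0.0))
    ae = np.sqrt(vc["AxEnv"]) * (LA @ rng.standard_normal((len(accs), len(envs))) @ LE.T)
    if GD is not None:
        d = _mvn(rng, GD, vc["D"])
        wD, VD = np.linalg.eigh(GD.values)
        LD = VD * np.sqrt(np.maximum(wD, 0.0))
        de = np.sqrt(vc["DxEnv"]) * (LD @ rng.standard_normal((len(accs), len(envs))) @ LE.T)
    else:
        d = np.zeros(len(accs))
        de = np.zeros((len(accs), len(envs)))

    qtl_terms = []
    for q in (qtl or []):
        if freq is None:
            raise ValueError("embedding QTL requires the frequency matrix")
        ids = list(freq.markers["id"])
        if q.marker not in ids:
            raise ValueError(f"QTL marker {q.marker!r} not in the panel")
        col = ids.index(q.marker)
        s = pd.Series(freq.p[:, col], index=freq.accessions).reindex(accs)
        qtl_terms.append({"marker": q.marker, "alpha": q.alpha,
                          "delta": dict(q.delta), "s": s})

    apos = {x: i for i, x in enumerate(accs)}
    epos = {x: j for j, x in enumerate(envs)}
    cell = np.full((len(accs), len(envs)), np.nan)
    scored = design.traits[trait]
    country_acc = design.country_accessions
    for country, year in scored:
        env = f"{country}-{year}"
        j = epos[env]
        for acc in country_acc[country]:
            i = apos[acc]
            val = mu + a[i] + e[j] + ae[i, j] + d[i] + de[i, j]
            for q in qtl_terms:
                val += q["s"][acc] * (q["alpha"] + q["delta"].get(country, 0.0))
            cell[i, j] = val

    # accession-mean-level residual is added at plot aggregation; simulate it
    # as a per-cell disturbance shared by the cell's plots
    cell_resid = rng.standard_normal(cell.shape) * np.sqrt(vc["residual"])
    cmap = {c.name: c for c in design.countries}
    year_eff = {env: rng.standard_normal() * np.sqrt(spatial.var_year)
                for env in envs}
    plots = []
    for country, year in scored:
        env = f"{country}-{year}"
        cspec = cmap[country]
        nrow, ncol = cspec.layout()
        Lr = _ar1_chol(spatial.rho_row, nrow)
        Lc = _ar1_chol(spatial.rho_col, ncol)
        members = country_acc[country]
        for t in range(cspec.n_trials):
            trial_eff = rng.standard_normal() * np.sqrt(spatial.var_trial)
            row_eff = np.sqrt(spatial.var_row) * (Lr @ rng.standard_normal(nrow))
            col_eff = np.sqrt(spatial.var_col) * (Lc @ rng.standard_normal(ncol))
            cells_rc = [(r, c) for r in range(nrow) for c in range(ncol)]
            layout = rng.permutation(len(cells_rc))[: len(members)]
            for acc, pos in zip(members, layout):
                r, c = cells_rc[pos]
                i, j = apos[acc], epos[env]
                val = (cell[i, j] + cell_resid[i, j] + year_eff[env] + trial_eff
                       + row_eff[r] + col_eff[c]
                       + rng.standard_normal() * np.sqrt(spatial.var_plot))
                plots.append((country, year, t + 1, t + 1, r + 1, c + 1,
                              acc, trait, val))
    plot_df = pd.DataFrame(plots, columns=["country", "year", "trial",
                                           "replicate", "row", "col",
                                           "accession", "trait", "value"])
    truth = TruthRecord(
        seed=seed, mu=mu, varcomp=vc,
        a=pd.Series(a, index=accs), d=pd.Series(d, index=accs),
        e=pd.Series(e, index=envs),
        ae=pd.DataFrame(ae, index=accs, columns=envs),
        de=pd.DataFrame(de, index=accs, columns=envs),
        qtl=qtl_terms,
        cell_means=pd.DataFrame(cell, index=accs, columns=envs),
        spatial=spatial,
    )
    return plot_df, truth


def simulate_stage2(
    design: DesignSpec,
    trait: str,
    G_A: Kernel,
    E: Kernel,
    G_D: Optional[Kernel] = None,
    varcomp: Optional[dict] = None,
    qtl: Optional[Sequence[QTL]] = None,
    freq: Optional[FrequencyMatrix] = None,
    mu: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame, TruthRecord]:
    """Draw stage-2 observations directly: cell means plus iid residual.

    Skips the plot-level expansion and stage-1 analysis; returns the
    observation vector, its index (accession, environment, country, year)
    and the truth record.  Used for studies of the stage-2 models where
    field effects are not of interest.
    """
    _, truth = simulate_phenotypes(design, trait, G_A, E, G_D, varcomp=varcomp,
                                   qtl=qtl, freq=freq, mu=mu, seed=seed,
                                   spatial=SpatialParams(var_year=0, var_trial=0,
                                                         var_row=0, var_col=0,
                                                         var_plot=0))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 915_261]))
    cm = truth.cell_means
    mask = ~cm.isna()
    rows = []
    for env in cm.columns:
        country, year = env.rsplit("-", 1)
        for acc in cm.index[mask[env]]:
            rows.append((acc, env, country, int(year), cm.loc[acc, env]))
    df = pd.DataFrame(rows, columns=["accession", "environment", "country",
                                     "year", "cell_mean"])
    resid = rng.standard_normal(len(df)) * np.sqrt(truth.varcomp["residual"])
    y = df["cell_mean"].to_numpy() + resid
    index = df[["accession", "environment", "country", "year"]]
    return y, index, truth
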