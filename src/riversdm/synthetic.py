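"""Synthetic riverscape, virtual species and survey generation.

The downstream modelling chain (survey filtering, predictor construction,
ensemble SDMs, richness stacking, scenario projection) is exercised end to
end on simulated data with known ground truth.  This module builds the three
ingredients:

* a **riverscape** — a table of river reaches along an elevation gradient
  with static catchment covariates and monthly air-temperature and discharge
  series (air temperature follows a configurable negative lapse rate, so
  elevation and temperature are strongly negatively associated by
  construction);
* a pool of **virtual species** with Gaussian niches on the environmental
  predictors, nested in a genus/family taxonomy;
* **surveys** — Bernoulli presence draws at the species' true occurrence
  probabilities, recorded at species, genus or family rank with configurable
  identification rates, mimicking partially identified field records.

All randomness flows through one `numpy.random.Generator` created from an
explicit seed; identical seeds give bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import env_predictors

__all__ = [
    "RiverscapeConfig",
    "Riverscape",
    "VirtualSpecies",
    "ScenarioSpec",
    "Surveys",
    "generate_riverscape",
    "generate_species_pool",
    "occurrence_probability",
    "occurrence_probability_matrix",
    "true_water_temperature",
    "true_predictor_matrix",
    "simulate_surveys",
    "apply_scenario",
]

#: Ground-truth water-temperature relation used by the generator:
#: WT = a + b * AT + c * AT * glacier_lake_pct.  Glacier- or lake-fed
#: reaches warm less per degree of air temperature (c < 0).
TRUE_WATER_TEMP_COEFS = (1.8, 0.72, -0.008)

REGIONS = (
    "Jura",
    "Plateau",
    "Northern Alps",
    "Central Eastern Alps",
    "Southern Alps",
    "Central Western Alps",
)


@dataclass(frozen=True)
class RiverscapeConfig:
    """Parameters of the synthetic riverscape.

    Units: elevations in m a.s.l., temperatures in °C, lapse rate in °C per
    km, discharge in m³/s, covers in percent of catchment area.
    """

    n_years: int = 1
    start_year: int = 2015
    extent_m: float = 100_000.0
    elevation_range: tuple[float, float] = (200.0, 3000.0)
    lapse_rate: float = -6.0
    sea_level_temp: float = 15.0
    seasonal_amplitude: float = 9.0
    air_noise_sd: float = 1.0
    discharge_base: float = 5.0
    discharge_noise_sd: float = 0.25
    glacier_elevation_min: float = 2200.0
    glacier_max_pct: float = 40.0
    n_glacier_cells: int = 20
    regions: tuple[str, ...] = REGIONS

    def validate(self) -> None:
        lo, hi = self.elevation_range
        if hi <= lo:
            raise ValueError("degenerate config: zero or negative elevation range")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if self.discharge_base <= 0:
            raise ValueError("discharge_base must be positive")


@dataclass
class Riverscape:
    """Reach table plus monthly forcing series and glacier cells.

    ``reaches`` columns: reach_id, x, y, elevation, region, slope,
    urban_cover, forest_cover, agri_cover, glacier_lake_pct.
    ``monthly`` columns (long format): reach_id, year, month, air_temp,
    discharge.  ``glacier_cells`` columns: reach_id, cell_id, elevation,
    area_pct.
    """

    reaches: pd.DataFrame
    monthly: pd.DataFrame
    glacier_cells: pd.DataFrame
    config: RiverscapeConfig

    def validate(self) -> None:
        r = self.reaches
        covers = r[["urban_cover", "forest_cover", "agri_cover"]]
        if ((covers < 0) | (covers > 100)).any().any():
            raise ValueError("cover percentages outside [0, 100]")
        if (covers.sum(axis=1) > 100 + 1e-9).any():
            raise ValueError("urban+forest+agri exceeds 100%")
        if ((r["glacier_lake_pct"] < 0) | (r["glacier_lake_pct"] > 100)).any():
            raise ValueError("glacier_lake_pct outside [0, 100]")
        if (self.monthly["discharge"] <= 0).any():
            raise ValueError("discharge must be strictly positive")

    def copy(self) -> "Riverscape":
        return Riverscape(
            self.reaches.copy(), self.monthly.copy(), self.glacier_cells.copy(), self.config
        )


def generate_riverscape(
    n_reaches: int, seed: int, config: RiverscapeConfig | None = None
) -> Riverscape:
    """Generate a synthetic riverscape of ``n_reaches`` reaches.

    Elevation increases (noisily) from south to north across the domain;
    air temperature decreases with elevation at ``config.lapse_rate`` °C/km;
    land cover shifts from urban/agricultural lowlands to forested mid
    elevations; reaches above ``glacier_elevation_min`` carry glacier cover
    discretised into equal-area cells used by the glacier-retreat heuristic.
    """
    if n_reaches < 10:
        raise ValueError("n_reaches must be >= 10")
    config = config or RiverscapeConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    lo, hi = config.elevation_range

    x = rng.uniform(0, config.extent_m, n_reaches)
    y = rng.uniform(0, config.extent_m, n_reaches)
    u = y / config.extent_m
    # mountainous mosaic: a weak south→north trend over mostly local relief,
    # so elevation (and everything it drives) is not a proxy for position
    rel = np.clip(0.3 * u + 0.7 * rng.beta(1.6, 1.6, n_reaches), 0, 1)
    elevation = np.clip(lo + (hi - lo) * rel + rng.normal(0, 60, n_reaches), lo, hi)
    rel = (elevation - lo) / (hi - lo)

    # region labels on a 3 (west-east) x 2 (south-north) grid
    col = np.minimum((x / config.extent_m * 3).astype(int), 2)
    row = np.minimum((y / config.extent_m * 2).astype(int), 1)
    region = np.asarray(config.regions)[row * 3 + col]

    slope = np.clip(4.0 + 10.0 * rel + rng.normal(0, 6.0, n_reaches), 0.1, 60.0)
    urban = np.clip(18.0 * np.exp(-1.2 * rel) * rng.lognormal(0, 0.8, n_reaches), 0, 80)
    agri = np.clip(16.0 * np.exp(-0.9 * rel) * rng.lognormal(0, 0.8, n_reaches), 0, 80)
    forest = np.clip(
        35.0 * np.exp(-0.5 * ((rel - 0.4) / 0.35) ** 2) * rng.lognormal(0, 0.5, n_reaches), 0, 90
    )
    total = urban + agri + forest
    scale = np.where(total > 95.0, 95.0 / np.maximum(total, 1e-9), 1.0)
    urban, agri, forest = urban * scale, agri * scale, forest * scale

    glaciated = elevation > config.glacier_elevation_min
    g_rel = np.clip(
        (elevation - config.glacier_elevation_min) / max(hi - config.glacier_elevation_min, 1.0),
        0,
        1,
    )
    glacier_pct = np.where(
        glaciated, config.glacier_max_pct * g_rel * rng.uniform(0.5, 1.0, n_reaches), 0.0
    )

    reach_id = np.array([f"R{i:05d}" for i in range(n_reaches)])
    reaches = pd.DataFrame(
        {
            "reach_id": reach_id,
            "x": x,
            "y": y,
            "elevation": elevation,
            "region": region,
            "slope": slope,
            "urban_cover": urban,
            "forest_cover": forest,
            "agri_cover": agri,
            "glacier_lake_pct": glacier_pct,
        }
    )

    # monthly series: seasonal sinusoid (July warmest) + lapse rate + noise
    months = np.arange(1, 13)
    years = np.arange(config.start_year, config.start_year + config.n_years)
    ym = pd.MultiIndex.from_product([years, months], names=["year", "month"]).to_frame(index=False)
    n_m = len(ym)
    # per-reach seasonal amplitude (continentality varies across catchments)
    amp = config.seasonal_amplitude * rng.uniform(0.45, 1.55, n_reaches)
    seasonal = np.cos(2 * np.pi * (ym["month"].to_numpy() - 7) / 12)
    base_temp = config.sea_level_temp + config.lapse_rate * elevation / 1000.0
    air = (
        base_temp[:, None]
        + amp[:, None] * seasonal[None, :]
        + rng.normal(0, config.air_noise_sd, (n_reaches, n_m))
    )

    # discharge: lognormal around an elevation-dependent level with a summer
    # (melt-driven) seasonal cycle whose amplitude grows with elevation
    q_level = config.discharge_base * np.exp(-0.8 * rel + rng.normal(0, 0.5, n_reaches))
    q_amp = 0.2 + 0.5 * rel
    q_seasonal = 1.0 + q_amp[:, None] * np.cos(
        2 * np.pi * (ym["month"].to_numpy()[None, :] - 6) / 12
    )
    discharge = (
        q_level[:, None]
        * np.clip(q_seasonal, 0.05, None)
        * np.exp(rng.normal(0, config.discharge_noise_sd, (n_reaches, n_m)))
    )

    monthly = pd.DataFrame(
        {
            "reach_id": np.repeat(reach_id, n_m),
            "year": np.tile(ym["year"].to_numpy(), n_reaches),
            "month": np.tile(ym["month"].to_numpy(), n_reaches),
            "air_temp": air.ravel(),
            "discharge": discharge.ravel(),
        }
    )

    # glacier cells: equal-area cells stacked up-glacier from the reach
    cells = []
    for rid, e, g in zip(reach_id, elevation, glacier_pct):
        if g <= 0:
            continue
        n_c = config.n_glacier_cells
        cell_elev = e + np.sort(rng.uniform(0, 1200.0, n_c))
        cells.append(
            pd.DataFrame(
                {
                    "reach_id": rid,
                    "cell_id": [f"{rid}c{j:02d}" for j in range(n_c)],
                    "elevation": cell_elev,
                    "area_pct": g / n_c,
                }
            )
        )
    glacier_cells = (
        pd.concat(cells, ignore_index=True)
        if cells
        else pd.DataFrame(columns=["reach_id", "cell_id", "elevation", "area_pct"])
    )

    rs = Riverscape(reaches, monthly, glacier_cells, config)
    rs.validate()
    return rs


# ---------------------------------------------------------------------------
# virtual species


@dataclass(frozen=True)
class VirtualSpecies:
    """A virtual species with a Gaussian niche on named predictors.

    ``niche`` maps predictor name -> (optimum mu, breadth sigma).  The true
    occurrence probability at predictor vector x is
    ``pmax * exp(-sum_j (x_j - mu_j)^2 / (2 sigma_j^2))``.
    """

    species_id: str
    genus: str
    family: str
    niche: Mapping[str, tuple[float, float]]
    pmax: float = 0.9

    def __post_init__(self):
        if not (0 <= self.pmax <= 1):
            raise ValueError("pmax must be in [0, 1]")
        for name, (_, sigma) in self.niche.items():
            if sigma <= 0:
                raise ValueError(f"niche breadth for {name!r} must be > 0")


def occurrence_probability(species: VirtualSpecies, predictors: Mapping[str, float]) -> float:
    """True occurrence probability of ``species`` at one predictor vector."""
    z2 = 0.0
    for name, (mu, sigma) in species.niche.items():
        if name not in predictors:
            raise KeyError(f"predictor {name!r} missing from input")
        val = float(predictors[name])
        if not np.isfinite(val):
            raise ValueError(f"predictor {name!r} is not finite")
        z2 += (val - mu) ** 2 / (2.0 * sigma**2)
    return float(species.pmax * np.exp(-z2))


def occurrence_probability_matrix(
    pool: Sequence[VirtualSpecies], X: pd.DataFrame
) -> pd.DataFrame:
    """True probabilities for every (row of X, species) pair."""
    out = {}
    for sp in pool:
        z2 = np.zeros(len(X))
        for name, (mu, sigma) in sp.niche.items():
            if name not in X.columns:
                raise KeyError(f"predictor {name!r} missing from input")
            z2 += (X[name].to_numpy(float) - mu) ** 2 / (2.0 * sigma**2)
        out[sp.species_id] = sp.pmax * np.exp(-z2)
    return pd.DataFrame(out, index=X.index)


def generate_species_pool(
    n_species: int,
    seed: int,
    niche_ranges: Mapping[str, tuple[float, float]],
    breadth_frac: tuple[float, float] = (0.2, 0.5),
    pmax_range: tuple[float, float] = (0.6, 0.98),
    n_families: int = 5,
    genera_per_family: int = 2,
) -> list[VirtualSpecies]:
    """Draw a taxonomically structured pool of Gaussian-niche species.

    Niche optima are uniform over ``niche_ranges`` (typically the observed
    range of each predictor); breadths are a fraction of the range width.
    Species are assigned round-robin to genera nested in families, so the
    taxonomy is a proper tree.
    """
    rng = np.random.default_rng(seed)
    families = [f"Fam{i:02d}" for i in range(n_families)]
    genera = [
        (f"Gen{i:02d}", families[i // genera_per_family % n_families])
        for i in range(n_families * genera_per_family)
    ]
    pool = []
    names = list(niche_ranges)
    for s in range(n_species):
        genus, family = genera[s % len(genera)]
        niche = {}
        for name in names:
            lo, hi = niche_ranges[name]
            width = hi - lo
            mu = rng.uniform(lo, hi)
            sigma = rng.uniform(*breadth_frac) * width
            niche[name] = (float(mu), float(sigma))
        pool.append(
            VirtualSpecies(
                species_id=f"Sp{s:03d}",
                genus=genus,
                family=family,
                niche=niche,
                pmax=float(rng.uniform(*pmax_range)),
            )
        )
    return pool


# ---------------------------------------------------------------------------
# ground truth


def true_water_temperature(
    air_temp: np.ndarray | float,
    glacier_lake_pct: np.ndarray | float,
    coefs: tuple[float, float, float] = TRUE_WATER_TEMP_COEFS,
) -> np.ndarray | float:
    """Generator's deterministic water-temperature relation (no noise)."""
    a, b, c = coefs
    return a + b * np.asarray(air_temp) + c * np.asarray(air_temp) * np.asarray(glacier_lake_pct)


def true_predictor_matrix(riverscape: Riverscape, year: int | None = None) -> pd.DataFrame:
    """Ground-truth environmental predictor matrix, one row per reach.

    Water temperature is derived from monthly air temperature through the
    generator's own (noiseless) relation; monthly series are summarised as
    mean / coefficient of variation, with the natural-log mean for
    discharge.  Indexed by reach_id.
    """
    year = year if year is not None else int(riverscape.monthly["year"].min())
    m = riverscape.monthly[riverscape.monthly["year"] == year]
    g = riverscape.reaches.set_index("reach_id")["glacier_lake_pct"]
    rows = {}
    for rid, sub in m.groupby("reach_id", sort=True):
        air = sub.sort_values("month")["air_temp"].to_numpy()
        q = sub.sort_values("month")["discharge"].to_numpy()
        # freezing floor: monthly water temperature cannot drop below 0 °C
        wt = np.clip(np.asarray(true_water_temperature(air, g[rid])), 0.0, None)
        wt_s = env_predictors.summarize_monthly(wt)
        q_s = env_predictors.summarize_monthly(q, log_mean=True)
        rows[rid] = {
            "water_temp_mean": wt_s["mean"],
            "water_temp_cv": wt_s["cv"],
            "discharge_logmean": q_s["log_mean"],
            "discharge_cv": q_s["cv"],
        }
    X = pd.DataFrame.from_dict(rows, orient="index")
    X.index.name = "reach_id"
    static = riverscape.reaches.set_index("reach_id")[
        ["slope", "urban_cover", "forest_cover", "agri_cover"]
    ]
    X = X.join(static).rename(
        columns={"urban_cover": "urban", "forest_cover": "forest", "agri_cover": "agri"}
    )
    return X[env_predictors.ENV_PREDICTORS]


# ---------------------------------------------------------------------------
# surveys


@dataclass
class Surveys:
    """Simulated survey records with retained ground truth.

    ``records``: site_id, date, taxon, rank, genus, family.
    ``sites``: site_id, reach_id, x, y, date.
    ``truth``: sites x species matrix of true occurrence probabilities.
    ``presence``: sites x species binary matrix of the realised draws.
    """

    records: pd.DataFrame
    sites: pd.DataFrame
    truth: pd.DataFrame
    presence: pd.DataFrame
    pool: list[VirtualSpecies]


def simulate_surveys(
    riverscape: Riverscape,
    pool: Sequence[VirtualSpecies],
    n_sites: int,
    ident_rates: Mapping[str, float],
    seed: int,
    predictors: pd.DataFrame | None = None,
    site_jitter_m: float = 10.0,
) -> Surveys:
    """Simulate one survey per site with imperfect taxonomic resolution.

    Each species' presence at a site is a Bernoulli draw at its true
    probability for the site's reach.  Every detected occurrence is recorded
    at species, genus or family rank with probabilities ``ident_rates``
    (keys ``species``/``genus``/``family``, summing to 1); coarser records
    inherit the true species' lineage.  Records identical after coarsening
    collapse to one row.
    """
    rates = np.array(
        [ident_rates.get("species", 0.0), ident_rates.get("genus", 0.0), ident_rates.get("family", 0.0)]
    )
    if not np.isclose(rates.sum(), 1.0):
        raise ValueError("ident_rates must sum to 1")
    n_reaches = len(riverscape.reaches)
    if n_sites > n_reaches:
        raise ValueError("n_sites cannot exceed the number of reaches")

    rng = np.random.default_rng(seed)
    idx = rng.choice(n_reaches, size=n_sites, replace=False)
    chosen = riverscape.reaches.iloc[idx].reset_index(drop=True)
    site_id = np.array([f"S{i:04d}" for i in range(n_sites)])
    year = int(riverscape.monthly["year"].min())
    dates = pd.to_datetime(
        {
            "year": year,
            "month": 6,
            "day": rng.integers(1, 29, n_sites),
        }
    ).astype(str)
    sites = pd.DataFrame(
        {
            "site_id": site_id,
            "reach_id": chosen["reach_id"].to_numpy(),
            "x": chosen["x"].to_numpy() + rng.uniform(-site_jitter_m, site_jitter_m, n_sites),
            "y": chosen["y"].to_numpy() + rng.uniform(-site_jitter_m, site_jitter_m, n_sites),
            "date": dates.to_numpy(),
        }
    )

    X = predictors if predictors is not None else true_predictor_matrix(riverscape)
    truth = occurrence_probability_matrix(pool, X.loc[sites["reach_id"]])
    truth.index = site_id
    truth.index.name = "site_id"

    draws = rng.random(truth.shape) < truth.to_numpy()
    presence = pd.DataFrame(draws.astype(int), index=truth.index, columns=truth.columns)

    by_id = {sp.species_id: sp for sp in pool}
    recs = []
    site_arr, sp_arr = np.nonzero(draws)
    ranks = np.array(["species", "genus", "family"])[
        rng.choice(3, size=len(site_arr), p=rates)
    ]
    cols = truth.columns.to_numpy()
    for i, j, rank in zip(site_arr, sp_arr, ranks):
        sp = by_id[cols[j]]
        if rank == "species":
            taxon, genus, family = sp.species_id, sp.genus, sp.family
        elif rank == "genus":
            taxon, genus, family = sp.genus, sp.genus, sp.family
        else:
            taxon, genus, family = sp.family, None, sp.family
        recs.append((site_id[i], sites["date"].iloc[i], taxon, rank, genus, family))
    records = pd.DataFrame(
        recs, columns=["site_id", "date", "taxon", "rank", "genus", "family"]
    ).drop_duplicates(subset=["site_id", "date", "taxon", "rank"], ignore_index=True)

    return Surveys(records=records, sites=sites, truth=truth, presence=presence, pool=list(pool))


def simulate_water_temperature_monitoring(
    riverscape: Riverscape,
    n_stations: int,
    n_months: int,
    seed: int,
    re_sd: tuple[float, float] = (0.5, 0.04),
    re_corr: float = 0.0,
    resid_sd: float = 0.7,
    coefs: tuple[float, float, float] = TRUE_WATER_TEMP_COEFS,
) -> pd.DataFrame:
    """Simulate a water-temperature monitoring network.

    ``n_stations`` reaches receive ``n_months`` repeated measures: water
    temperature follows the generator's fixed relation on monthly air
    temperature and glacier/lake cover, plus a station-level random
    intercept and random air-temperature slope (standard deviations
    ``re_sd``, correlation ``re_corr``) and residual noise ``resid_sd``.
    Columns: station, month_index, air_temp, glacier_lake_pct, water_temp.
    """
    rng = np.random.default_rng(seed)
    n_reaches = len(riverscape.reaches)
    if n_stations > n_reaches:
        raise ValueError("n_stations cannot exceed the number of reaches")
    # stratified network: glacier/lake-fed reaches are deliberately
    # oversampled (up to half the stations) so the cover interaction is
    # identifiable, as a monitoring network designed for it would be
    glaciated = np.flatnonzero(riverscape.reaches["glacier_lake_pct"].to_numpy() > 0)
    others = np.setdiff1d(np.arange(n_reaches), glaciated)
    n_g = min(len(glaciated), n_stations // 2)
    idx = np.concatenate(
        [
            rng.choice(glaciated, size=n_g, replace=False),
            rng.choice(others, size=n_stations - n_g, replace=False),
        ]
    )
    chosen = riverscape.reaches.iloc[idx]
    cfg = riverscape.config

    sd0, sd1 = re_sd
    cov = np.array(
        [[sd0**2, re_corr * sd0 * sd1], [re_corr * sd0 * sd1, sd1**2]]
    )
    re = rng.multivariate_normal([0.0, 0.0], cov, size=n_stations)

    months = np.arange(n_months)
    rows = []
    for s, (_, reach) in enumerate(chosen.iterrows()):
        base = cfg.sea_level_temp + cfg.lapse_rate * reach["elevation"] / 1000.0
        seasonal = cfg.seasonal_amplitude * np.cos(2 * np.pi * ((months % 12) + 1 - 7) / 12)
        air = base + seasonal + rng.normal(0, cfg.air_noise_sd, n_months)
        wt = (
            np.asarray(true_water_temperature(air, reach["glacier_lake_pct"], coefs))
            + re[s, 0]
            + re[s, 1] * air
            + rng.normal(0, resid_sd, n_months)
        )
        rows.append(
            pd.DataFrame(
                {
                    "station": f"W{s:03d}",
                    "month_index": months,
                    "air_temp": air,
                    "glacier_lake_pct": reach["glacier_lake_pct"],
                    "water_temp": wt,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# scenarios


@dataclass(frozen=True)
class ScenarioSpec:
    """A climate forcing perturbation applied to a riverscape.

    ``temp_offset`` shifts every monthly air temperature (°C);
    ``discharge_multiplier`` scales every monthly discharge;
    ``glacier_replace_fraction`` q removes the lowest-elevation fraction q of
    glacier cells (deglaciation to bare rock).
    """

    rcp: str = "RCP2.6"
    period: str = "t1"
    temp_offset: float = 0.0
    discharge_multiplier: float = 1.0
    glacier_replace_fraction: float = 0.0

    def __post_init__(self):
        if self.discharge_multiplier <= 0:
            raise ValueError("discharge_multiplier must be > 0")
        if not (0 <= self.glacier_replace_fraction <= 1):
            raise ValueError("glacier_replace_fraction must be in [0, 1]")

    # glacier-replacement fractions for the two pathways and the two future
    # decades; the near-term decade is the unperturbed baseline
    _GLACIER_Q = {
        ("RCP2.6", "t2"): 0.45,
        ("RCP8.5", "t2"): 0.50,
        ("RCP2.6", "t3"): 0.60,
        ("RCP8.5", "t3"): 0.90,
    }
    _TEMP_OFFSET = {
        ("RCP2.6", "t2"): 1.0,
        ("RCP8.5", "t2"): 2.5,
        ("RCP2.6", "t3"): 1.0,
        ("RCP8.5", "t3"): 4.2,
    }
    _Q_MULT = {
        ("RCP2.6", "t2"): 0.97,
        ("RCP8.5", "t2"): 0.93,
        ("RCP2.6", "t3"): 0.97,
        ("RCP8.5", "t3"): 0.88,
    }

    @classmethod
    def default(cls, rcp: str, period: str) -> "ScenarioSpec":
        """Default scenario set: baseline decade t1 is the identity; the
        mid- and end-century decades (t2, t3) combine warming, a discharge
        reduction and staged glacier loss, stronger under the high-emission
        pathway."""
        if period == "t1":
            return cls(rcp=rcp, period="t1")
        key = (rcp, period)
        if key not in cls._GLACIER_Q:
            raise KeyError(f"unknown scenario {key}")
        return cls(
            rcp=rcp,
            period=period,
            temp_offset=cls._TEMP_OFFSET[key],
            discharge_multiplier=cls._Q_MULT[key],
            glacier_replace_fraction=cls._GLACIER_Q[key],
        )


def apply_scenario(riverscape: Riverscape, scenario: ScenarioSpec) -> Riverscape:
    """Return a new riverscape under the scenario's forcing perturbation."""
    out = riverscape.copy()
    out.monthly["air_temp"] = out.monthly["air_temp"] + scenario.temp_offset
    out.monthly["discharge"] = out.monthly["discharge"] * scenario.discharge_multiplier
    q = scenario.glacier_replace_fraction
    if q > 0 and len(out.glacier_cells):
        kept = env_predictors.glacier_retreat(out.glacier_cells, q)
        out.glacier_cells = kept
        new_pct = kept.groupby("reach_id")["area_pct"].sum()
        out.reaches["glacier_lake_pct"] = (
            out.reaches["reach_id"].map(new_pct).fillna(0.0).to_numpy()
        )
    out.validate()
    return out
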