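"""Synthetic Pollard-walk monitoring data with known ground truth.

Generates weekly transect counts for a multi-species butterfly monitoring
scheme: sites along a latitudinal temperature gradient, species with
uni-/bi-/multivoltine flight curves expressed in accumulated degree-day time,
log-normal random effects for site, year and site-x-year (observation), and
weeks dropped completely at random.  The generative model for a surveyed
site-year-week is

    E[count] = exp(b0 + beta_year * year_c + site + year + obs)
               * (flight-curve mass in the week) * duration / duration_mean

so the downstream trend model is fit to data that actually follow its
assumed structure, and every latent quantity is returned in a truth record
for recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "SpeciesSpec",
    "SimConfig",
    "SimResult",
    "simulate_sites",
    "simulate_temperatures",
    "simulate_monitoring",
    "simulate_index_table",
    "default_species_pool",
    "config_from_yaml",
    "config_to_yaml",
    "write_survey_csv",
    "write_truth_json",
]

SEASON_START_DOY = 91  # April 1 (non-leap)
DAYS_PER_WEEK = 7

_VOLTINISM_BROODS = {"univoltine": 1, "bivoltine": 2, "multivoltine": 3}


@dataclass
class SpeciesSpec:
    """True parameters for one simulated species."""

    species_id: str
    voltinism: str
    brood_peaks_gdd: list[float]
    brood_sd_gdd: float
    baseline_log_abundance: float
    annual_trend: float = 0.0
    migratory: bool = False
    traits: dict | None = None

    def __post_init__(self) -> None:
        self.brood_peaks_gdd = [float(p) for p in self.brood_peaks_gdd]
        self.brood_sd_gdd = float(self.brood_sd_gdd)
        self.baseline_log_abundance = float(self.baseline_log_abundance)
        self.annual_trend = float(self.annual_trend)
        self.migratory = bool(self.migratory)
        if self.voltinism not in _VOLTINISM_BROODS:
            raise ValueError(f"unknown voltinism {self.voltinism!r}")
        n_min = _VOLTINISM_BROODS[self.voltinism]
        n = len(self.brood_peaks_gdd)
        ok = n == n_min if self.voltinism != "multivoltine" else n >= 3
        if not ok:
            raise ValueError(
                f"{self.species_id}: {self.voltinism} requires "
                f"{'>=3' if self.voltinism == 'multivoltine' else n_min} brood peaks, got {n}"
            )
        if not self.brood_sd_gdd > 0:
            raise ValueError("brood_sd_gdd must be > 0")


@dataclass
class SimConfig:
    """Configuration of a synthetic monitoring scheme.

    Defaults follow the calibration of the Ohio-style scheme the package
    targets: random-effect SDs 0.417 (site), 0.121 (year), 0.278
    (site x year observation) on the log scale, 30-week April-October
    seasons with on average 23 of 30 weeks surveyed, and a mean survey
    duration of 85 minutes.
    """

    species_specs: list[SpeciesSpec]
    n_sites: int = 50
    n_years: int = 21
    weeks_per_season: int = 30
    sd_site: float = 0.417
    sd_year: float = 0.121
    sd_obs: float = 0.278
    missing_week_prob: float = 7.0 / 30.0
    duration_mean_minutes: float = 85.0
    duration_sd_minutes: float = 25.0
    listlength_effect: float = 0.0
    temp_gradient_per_degree_lat: float = -2.5
    start_year: int = 1996
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sd_site, self.sd_year, self.sd_obs) < 0:
            raise ValueError("random-effect SDs must be >= 0")
        if not 0 <= self.missing_week_prob < 1:
            raise ValueError("missing_week_prob must be in [0, 1)")
        if self.weeks_per_season < 2:
            raise ValueError("weeks_per_season must be >= 2")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")
        if not self.species_specs:
            raise ValueError("at least one species required")


@dataclass
class SimResult:
    """Survey table plus latent truth from one simulated dataset."""

    sites: pd.DataFrame        # site_id, latitude, longitude
    surveys: pd.DataFrame      # site_id, year, week, doy, duration_min, surveyed
    counts: pd.DataFrame       # long: site_id, year, week, species_id, count (surveyed only)
    temperatures: pd.DataFrame  # site_id, year, doy, tmin, tmax
    truth: dict


def default_species_pool(
    n_species: int,
    rng: np.random.Generator,
    annual_trend: float = 0.0,
    baseline_range: tuple[float, float] = (np.log(30.0), np.log(400.0)),
    migratory_fraction: float = 0.15,
) -> list[SpeciesSpec]:
    """A mixed-voltinism species roster with randomized flight-curve truth.

    Brood peaks sit in the degree-day ranges a temperate season produces
    (roughly 150-2600 accumulated GDD base 5 between April and October);
    seasonal totals span roughly 30-400 individuals per site-year at
    baseline.  All species share ``annual_trend`` (log-scale per year).
    """
    voltinism_cycle = ["univoltine", "bivoltine", "multivoltine"]
    specs = []
    for i in range(n_species):
        v = voltinism_cycle[i % 3]
        if v == "univoltine":
            peaks = [float(rng.uniform(600, 1300))]
        elif v == "bivoltine":
            first = float(rng.uniform(350, 650))
            peaks = [first, first + float(rng.uniform(650, 950))]
        else:
            first = float(rng.uniform(250, 450))
            gap = float(rng.uniform(550, 750))
            peaks = [first, first + gap, first + 2 * gap]
        specs.append(
            SpeciesSpec(
                species_id=f"sp{i + 1:03d}",
                voltinism=v,
                brood_peaks_gdd=peaks,
                brood_sd_gdd=float(rng.uniform(80, 150)),
                baseline_log_abundance=float(rng.uniform(*baseline_range)),
                annual_trend=annual_trend,
                migratory=bool(rng.random() < migratory_fraction),
            )
        )
    return specs


def simulate_sites(n_sites: int, rng: np.random.Generator) -> pd.DataFrame:
    """Site table with a latitude spread of ~3.5 degrees (Ohio-like extent)."""
    lat = rng.uniform(38.5, 42.0, n_sites)
    lon = rng.uniform(-84.5, -80.5, n_sites)
    return pd.DataFrame(
        {"site_id": [f"S{i + 1:03d}" for i in range(n_sites)],
         "latitude": lat, "longitude": lon}
    )


def simulate_temperatures(
    sites: pd.DataFrame,
    years: int,
    seed: int | np.random.Generator = 0,
    start_year: int = 1996,
    temp_gradient_per_degree_lat: float = -2.5,
    mean_annual_c: float = 11.0,
    seasonal_amplitude_c: float = 13.0,
    diurnal_range_c: float = 10.0,
    noise_sd_c: float = 2.0,
    days_per_year: int = 365,
) -> pd.DataFrame:
    """Daily tmin/tmax per site and year.

    Daily mean temperature is a sinusoid peaking in late July plus a site
    offset proportional to latitude (northern sites colder for a negative
    gradient) plus iid day-level noise; tmin/tmax sit half a diurnal range
    below/above the mean, so tmax >= tmin holds by construction.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    lat = np.asarray(sites["latitude"], dtype=float)
    if not np.all(np.isfinite(lat)):
        raise ValueError("non-finite latitude in site table")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    ref_lat = lat.mean()
    doy = np.arange(1, days_per_year + 1)
    seasonal = mean_annual_c + seasonal_amplitude_c * np.cos(
        2 * np.pi * (doy - 200) / days_per_year
    )
    frames = []
    for site_id, site_lat in zip(sites["site_id"], lat):
        offset = temp_gradient_per_degree_lat * (site_lat - ref_lat)
        for j in range(years):
            noise = rng.normal(0.0, noise_sd_c, days_per_year) if noise_sd_c > 0 else 0.0
            tmean = seasonal + offset + noise
            frames.append(
                pd.DataFrame(
                    {
                        "site_id": site_id,
                        "year": start_year + j,
                        "doy": doy,
                        "tmin": tmean - diurnal_range_c / 2.0,
                        "tmax": tmean + diurnal_range_c / 2.0,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def simulate_monitoring(config: SimConfig) -> SimResult:
    """Simulate one complete monitoring dataset under ``config``.

    Returns the survey schedule (with MCAR-missing weeks), long-format
    per-species counts for surveyed weeks, the daily temperature series the
    phenology stage will consume, and a truth record holding every latent
    effect and parameter.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_site, rng_temp, rng_eff, rng_obs, rng_count = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    sites = simulate_sites(config.n_sites, rng_site)
    temps = simulate_temperatures(
        sites,
        config.n_years,
        seed=rng_temp,
        start_year=config.start_year,
        temp_gradient_per_degree_lat=config.temp_gradient_per_degree_lat,
    )

    years = np.arange(config.start_year, config.start_year + config.n_years)
    year_c = years - years.mean()
    weeks = config.weeks_per_season

    site_eff = rng_eff.normal(0.0, config.sd_site, config.n_sites) if config.sd_site > 0 else np.zeros(config.n_sites)
    year_eff = rng_eff.normal(0.0, config.sd_year, config.n_years) if config.sd_year > 0 else np.zeros(config.n_years)
    obs_eff = (
        rng_eff.normal(0.0, config.sd_obs, (config.n_sites, config.n_years))
        if config.sd_obs > 0
        else np.zeros((config.n_sites, config.n_years))
    )
    quality = rng_eff.normal(0.0, 1.0, (config.n_sites, config.n_years))

    # survey schedule: week kept with prob 1 - missing_week_prob, truncated
    # log-normal durations (>= 10 min)
    surveyed = rng_obs.random((config.n_sites, config.n_years, weeks)) >= config.missing_week_prob
    mu_ln = np.log(config.duration_mean_minutes**2 /
                   np.sqrt(config.duration_mean_minutes**2 + config.duration_sd_minutes**2))
    sd_ln = np.sqrt(np.log(1 + (config.duration_sd_minutes / config.duration_mean_minutes) ** 2))
    durations = np.maximum(rng_obs.lognormal(mu_ln, sd_ln, surveyed.shape), 10.0)

    # accumulated degree-days per site-year (base 5, simple-average method)
    from .phenology import degree_day_table

    gdd_tab = degree_day_table(temps)
    gdd_map = {
        key: grp["gdd"].to_numpy()
        for key, grp in gdd_tab.groupby(["site_id", "year"], sort=False)
    }

    week_idx = np.arange(1, weeks + 1)
    doy_mid = SEASON_START_DOY + DAYS_PER_WEEK * (week_idx - 1) + 3

    # weekly flight-curve GDD bounds per site-year: (n_sites, n_years, weeks+1)
    site_ids = list(sites["site_id"])
    week_starts = SEASON_START_DOY + DAYS_PER_WEEK * np.arange(weeks + 1)
    bounds_gdd = np.empty((config.n_sites, config.n_years, weeks + 1))
    for si, site_id in enumerate(site_ids):
        for yi, year in enumerate(years):
            gdd = gdd_map[(site_id, year)]
            bounds_gdd[si, yi] = np.interp(week_starts, np.arange(1, len(gdd) + 1), gdd)

    log_base = (
        site_eff[:, None]
        + year_eff[None, :]
        + obs_eff
        + config.listlength_effect * quality
    )  # (n_sites, n_years)
    effort = np.where(surveyed, durations / config.duration_mean_minutes, 0.0)

    svy_flat = surveyed.reshape(-1)
    surveys = pd.DataFrame(
        {
            "site_id": np.repeat(site_ids, config.n_years * weeks),
            "year": np.tile(np.repeat(years, weeks), config.n_sites),
            "week": np.tile(week_idx, config.n_sites * config.n_years),
            "doy": np.tile(doy_mid, config.n_sites * config.n_years),
            "duration_min": np.where(svy_flat, durations.reshape(-1), np.nan),
            "surveyed": svy_flat,
        }
    )

    count_frames = []
    for spec in config.species_specs:
        peaks = np.asarray(spec.brood_peaks_gdd, dtype=float)
        cdf = stats.norm.cdf(
            bounds_gdd[..., None], loc=peaks, scale=spec.brood_sd_gdd
        ).mean(axis=-1)
        mass = np.diff(cdf, axis=-1)  # (n_sites, n_years, weeks)
        if np.any(mass.sum(axis=-1) < 1e-6):
            warnings.warn(
                f"{spec.species_id}: flight curve has no mass inside the season "
                "for at least one site-year; counts there are all zero",
                stacklevel=2,
            )
        lam = (
            np.exp(
                spec.baseline_log_abundance
                + spec.annual_trend * year_c[None, :, None]
                + log_base[..., None]
            )
            * mass
            * effort
        )
        c = rng_count.poisson(lam).reshape(-1)
        count_frames.append(
            pd.DataFrame(
                {
                    "site_id": surveys["site_id"][svy_flat],
                    "year": surveys["year"][svy_flat],
                    "week": surveys["week"][svy_flat],
                    "species_id": spec.species_id,
                    "count": c[svy_flat].astype(int),
                }
            )
        )

    counts = pd.concat(count_frames, ignore_index=True)

    truth = {
        "config": config,
        "species": {
            s.species_id: {
                "annual_trend": s.annual_trend,
                "baseline_log_abundance": s.baseline_log_abundance,
                "voltinism": s.voltinism,
                "brood_peaks_gdd": list(s.brood_peaks_gdd),
                "brood_sd_gdd": s.brood_sd_gdd,
                "migratory": s.migratory,
            }
            for s in config.species_specs
        },
        "site_effects": dict(zip(sites["site_id"], site_eff)),
        "year_effects": dict(zip((int(y) for y in years), year_eff)),
        "obs_effects": {
            (site_id, int(year)): float(obs_eff[si, yi])
            for si, site_id in enumerate(sites["site_id"])
            for yi, year in enumerate(years)
        },
    }
    return SimResult(sites=sites, surveys=surveys, counts=counts,
                     temperatures=temps, truth=truth)


def simulate_index_table(
    n_sites: int,
    n_years: int,
    beta0: float,
    beta_year: float,
    beta_listlength: float = 0.0,
    sd_site: float = 0.417,
    sd_year: float = 0.121,
    sd_obs: float = 0.278,
    duration_mean_minutes: float = 85.0,
    weeks_per_season: int = 30,
    start_year: int = 1996,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate a population-index table directly from the trend model.

    Skips the survey/phenology stages: one Poisson draw per site-year whose
    log mean is beta0 + beta_year*year_c + beta_listlength*ll_c +
    log(projected duration) + site + year + observation effects.  Used for
    estimator-level tests where the survey process is not the object of
    study.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    years = np.arange(start_year, start_year + n_years)
    site_ids = [f"S{i + 1:03d}" for i in range(n_sites)]
    site_eff = rng.normal(0, sd_site, n_sites) if sd_site > 0 else np.zeros(n_sites)
    year_eff = rng.normal(0, sd_year, n_years) if sd_year > 0 else np.zeros(n_years)

    grid = pd.MultiIndex.from_product([site_ids, years], names=["site_id", "year"]).to_frame(index=False)
    n = len(grid)
    obs_eff = rng.normal(0, sd_obs, n) if sd_obs > 0 else np.zeros(n)
    ll = rng.normal(8.0, 2.0, n)
    dur = weeks_per_season * np.maximum(rng.normal(duration_mean_minutes, 10.0, n), 10.0)

    year_c = grid["year"].to_numpy() - years.mean()
    eta = (
        beta0
        + beta_year * year_c
        + beta_listlength * (ll - ll.mean())
        + np.log(dur)
        + site_eff[grid["site_id"].map({s: i for i, s in enumerate(site_ids)})]
        + year_eff[grid["year"].map({int(y): i for i, y in enumerate(years)})]
        + obs_eff
    )
    grid["index"] = rng.poisson(np.exp(eta)).astype(float)
    grid["mean_list_length"] = ll
    grid["projected_duration_minutes"] = dur
    grid["n_surveys"] = weeks_per_season
    grid["species_id"] = "total"
    return grid


# ---------------------------------------------------------------------------
# serialization

def config_to_yaml(config: SimConfig, path) -> None:
    d = dataclasses.asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def config_from_yaml(path) -> SimConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["species_specs"] = [SpeciesSpec(**s) for s in d["species_specs"]]
    return SimConfig(**d)


def write_survey_csv(result: SimResult, path) -> None:
    """Long-format survey CSV: site,year,week,date,duration_min,species,count."""
    merged = result.counts.merge(
        result.surveys[["site_id", "year", "week", "doy", "duration_min"]],
        on=["site_id", "year", "week"],
    )
    merged = merged.rename(columns={"doy": "date"})[
        ["site_id", "year", "week", "date", "duration_min", "species_id", "count"]
    ]
    merged.to_csv(path, index=False)


def write_truth_json(result: SimResult, path) -> None:
    truth = result.truth
    out = {
        "config": dataclasses.asdict(truth["config"]),
        "species": truth["species"],
        "site_effects": {k: float(v) for k, v in truth["site_effects"].items()},
        "year_effects": {str(k): float(v) for k, v in truth["year_effects"].items()},
        "obs_effects": {f"{s}|{y}": v for (s, y), v in truth["obs_effects"].items()},
    }
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1)
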