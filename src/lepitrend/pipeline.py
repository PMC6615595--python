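"""End-to-end orchestration: surveys -> phenology -> indices -> trends.

Thin glue over the computational modules so the analysis drivers, the test
suite, and the acceptance script all execute the identical pipeline.  Also
provides the end-to-end parameter-recovery experiment: simulate a scheme
with a known common trend, run the full pipeline, and compare the
estimated annual rate with truth.
"""

from __future__ import annotations

import json
import platform
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import indices as idx
from . import phenology as phen
from . import simdata, trends

__all__ = [
    "PipelineResult",
    "complete_all_species",
    "run_pipeline",
    "recovery_experiment",
    "write_manifest",
]


@dataclass
class PipelineResult:
    sim: simdata.SimResult
    completed: pd.DataFrame
    index_table: pd.DataFrame
    filtered: pd.DataFrame
    eligibility: dict
    total_fit: trends.TrendFit
    species_fits: dict = field(default_factory=dict)
    skipped_species: list = field(default_factory=list)
    flight_models: dict = field(default_factory=dict)


def complete_all_species(
    sim: simdata.SimResult,
    min_surveys_phenology: int = 5,
    alpha_grid: tuple = (1.0, 10.0, 100.0),
) -> tuple[pd.DataFrame, dict, list]:
    """Fit flight curves and impute missing weeks for every species.

    Returns the completed long count table (site, year, week, species,
    count, imputed), the per-species flight-curve models, and the species
    skipped for lacking enough phenology data.
    """
    surveys = phen.eligible_for_phenology(sim.surveys, min_surveys=min_surveys_phenology)
    gdd = phen.degree_day_table(sim.temperatures)
    sched = surveys.merge(gdd, on=["site_id", "year", "doy"], how="left")
    sched = sched.merge(sim.sites, on="site_id", how="left")

    completed_frames, models, skipped = [], {}, []
    for sp in sorted(sim.counts["species_id"].unique()):
        sp_counts = sim.counts[sim.counts["species_id"] == sp]
        grid = sched.merge(
            sp_counts[["site_id", "year", "week", "count"]],
            on=["site_id", "year", "week"], how="left",
        )
        # surveyed weeks with no row in the long table are true zeros
        grid.loc[grid["surveyed"] & grid["count"].isna(), "count"] = 0.0
        train = grid[grid["surveyed"]]
        try:
            model = phen.fit_flight_curve(
                train, species_id=sp, alpha_grid=alpha_grid
            )
        except ValueError as err:
            skipped.append((sp, str(err)))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            filled = phen.impute_missing_counts(model, grid)
        filled["species_id"] = sp
        completed_frames.append(
            filled[["site_id", "year", "week", "species_id", "count", "imputed"]]
        )
        models[sp] = model
    if not completed_frames:
        raise ValueError("no species had enough data for phenology models")
    return pd.concat(completed_frames, ignore_index=True), models, skipped


def run_pipeline(
    config: simdata.SimConfig,
    fit_species: bool = False,
    min_surveys_phenology: int = 5,
) -> PipelineResult:
    """Run the full analysis on one simulated monitoring dataset."""
    sim = simdata.simulate_monitoring(config)
    completed, models, skipped = complete_all_species(
        sim, min_surveys_phenology=min_surveys_phenology
    )
    index_table = idx.build_population_index_table(
        completed, sim.surveys, weeks_per_season=config.weeks_per_season
    )
    filtered, eligibility = idx.apply_trend_filters(index_table, sim.surveys)
    total = idx.total_abundance_indices(filtered)
    total_fit = trends.fit_trend_glmm(total)

    species_fits = {}
    if fit_species:
        for sp, ok in eligibility.items():
            if not ok:
                continue
            rows = idx.species_trend_rows(filtered, sp)
            try:
                species_fits[sp] = trends.fit_trend_glmm(rows)
            except (ValueError, trends.ConvergenceError) as err:
                skipped.append((sp, f"trend fit failed: {err}"))
    return PipelineResult(
        sim=sim,
        completed=completed,
        index_table=index_table,
        filtered=filtered,
        eligibility=eligibility,
        total_fit=total_fit,
        species_fits=species_fits,
        skipped_species=skipped,
        flight_models=models,
    )


def recovery_experiment(
    n_replicates: int,
    seed: int,
    n_sites: int = 50,
    n_years: int = 21,
    n_species: int = 12,
    annual_rate_percent: float = -2.0,
    sd_site: float = 0.417,
    sd_year: float = 0.121,
    sd_obs: float = 0.278,
) -> pd.DataFrame:
    """End-to-end parameter recovery for the annual trend.

    Each replicate simulates a scheme in which every species declines at
    ``annual_rate_percent`` per year with the stated variance components,
    runs phenology -> indices -> GLMM on total abundance, and records the
    estimated year coefficient, its SE, and whether truth lies within 2 SE.
    """
    truth_beta = np.log1p(annual_rate_percent / 100.0)
    ss = np.random.SeedSequence(seed)
    rows = []
    for rep, child in enumerate(ss.spawn(n_replicates)):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(rep_seed)
        specs = simdata.default_species_pool(n_species, rng, annual_trend=truth_beta)
        config = simdata.SimConfig(
            species_specs=specs, n_sites=n_sites, n_years=n_years,
            sd_site=sd_site, sd_year=sd_year, sd_obs=sd_obs, seed=rep_seed,
        )
        result = run_pipeline(config)
        fit = result.total_fit
        rows.append(
            {
                "replicate": rep,
                "seed": rep_seed,
                "beta_year": fit.beta_year,
                "se": fit.se["year"],
                "annual_rate_percent": trends.annualized_rate(fit),
                "truth_beta": truth_beta,
                "covered_2se": bool(abs(fit.beta_year - truth_beta) <= 2 * fit.se["year"]),
            }
        )
    return pd.DataFrame(rows)


def write_manifest(path, entries: dict) -> None:
    """JSON run manifest: inputs, seeds, package versions, thresholds."""
    import lepitrend

    manifest = {
        "lepitrend_version": lepitrend.__version__,
        "python": platform.python_version(),
        **entries,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
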