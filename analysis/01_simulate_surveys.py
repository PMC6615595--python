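"""Simulate the synthetic Pollard-walk monitoring scheme.

Generates the study dataset every later step consumes: a 50-site,
21-season scheme of 12 species declining at a common -2% per year, with
the calibrated random-effect SDs (site 0.417, year 0.121, observation
0.278) and ~23 of 30 weeks surveyed.  Writes the simulation config (the
single source of truth for scripts 02-04), the survey/truth files, and a
summary of the realized sampling.

Usage: python analysis/01_simulate_surveys.py [--seed 1] [--out results]
"""

import argparse
import pathlib

import numpy as np

from lepitrend import pipeline, simdata


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--sites", type=int, default=50)
    ap.add_argument("--years", type=int, default=21)
    ap.add_argument("--species", type=int, default=12)
    ap.add_argument("--annual-rate", type=float, default=-2.0,
                    help="true common annual trend, percent per year")
    ap.add_argument("--out", type=pathlib.Path, default=pathlib.Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(args.seed)
    specs = simdata.default_species_pool(
        args.species, rng, annual_trend=np.log1p(args.annual_rate / 100.0)
    )
    config = simdata.SimConfig(
        species_specs=specs, n_sites=args.sites, n_years=args.years, seed=args.seed
    )
    simdata.config_to_yaml(config, args.out / "sim_config.yaml")

    sim = simdata.simulate_monitoring(config)
    simdata.write_survey_csv(sim, args.out / "surveys_long.csv")
    simdata.write_truth_json(sim, args.out / "truth.json")

    obs = sim.surveys[sim.surveys["surveyed"]]
    weeks_per_sy = obs.groupby(["site_id", "year"])["week"].size()
    print(f"simulated {args.sites} sites x {args.years} years x {args.species} species "
          f"(seed {args.seed})")
    print(f"  surveys: {len(obs)} of {len(sim.surveys)} site-weeks "
          f"({1 - len(obs) / len(sim.surveys):.1%} missing; target 23.3%)")
    print(f"  median weeks surveyed per site-year: {weeks_per_sy.median():.0f} of 30")
    print(f"  mean survey duration: {obs['duration_min'].mean():.0f} min (target 85)")
    print(f"  total butterflies counted: {sim.counts['count'].sum():,}")
    pipeline.write_manifest(args.out / "manifest_01.json", {
        "step": "simulate_surveys", "seed": args.seed,
        "n_sites": args.sites, "n_years": args.years, "n_species": args.species,
        "true_annual_rate_percent": args.annual_rate,
    })


if __name__ == "__main__":
    main()
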