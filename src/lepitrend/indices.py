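"""Population indices per site x year x species, with sampling covariates.

The population index integrates completed (observed + imputed) weekly
counts over the season with the trapezoid rule, in butterfly-weeks.  Each
index row carries two effort covariates for the trend model: the mean
list-length (species recorded per survey, a detectability proxy) and the
projected total duration had every week been surveyed at that site-year's
mean duration.  Inclusion filters follow the scheme's design: trend sites
need three or more years with ten or more surveys each; species-level
trends additionally need presence at five or more sites in ten or more
years.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "trapezoid_index",
    "mean_list_length",
    "projected_duration",
    "build_population_index_table",
    "apply_trend_filters",
    "total_abundance_indices",
    "species_trend_rows",
]


def trapezoid_index(weekly_counts) -> float:
    """Trapezoid-rule integral of a complete weekly count series.

    Weeks are unit-spaced, so the index is sum_i (c_i + c_{i+1}) / 2 in
    butterfly-weeks.  Requires length >= 2 and no missing or negative
    entries (imputation happens upstream).
    """
    c = np.asarray(weekly_counts, dtype=float)
    if c.ndim != 1 or len(c) < 2:
        raise ValueError("need an ordered series of >= 2 weekly counts")
    if np.any(np.isnan(c)):
        raise ValueError("missing weekly counts; impute before integrating")
    if np.any(c < 0):
        raise ValueError("negative weekly counts")
    return float(np.trapezoid(c))


def mean_list_length(counts: pd.DataFrame, surveyed_weeks) -> float:
    """Mean number of species recorded per survey in one site-year.

    ``counts`` is the long count table restricted to one site-year (observed
    surveys only); ``surveyed_weeks`` lists the weeks actually surveyed, so
    surveys recording zero species still enter the mean as 0.
    """
    surveyed_weeks = list(surveyed_weeks)
    if len(surveyed_weeks) == 0:
        raise ValueError("mean list-length undefined without surveyed weeks")
    present = counts[counts["count"] > 0]
    per_week = present.groupby("week")["species_id"].nunique()
    per_week = per_week.reindex(surveyed_weeks, fill_value=0)
    return float(per_week.mean())


def projected_duration(durations, weeks_per_season: int = 30) -> float:
    """Projected season-total survey minutes for one site-year.

    weeks_per_season times the mean of the observed durations: the total
    duration had every week been surveyed at the site-year's mean duration.
    """
    d = np.asarray(durations, dtype=float)
    if len(d) == 0:
        raise ValueError("no surveyed weeks with durations")
    if np.any(np.isnan(d)):
        raise ValueError("missing survey durations")
    return float(weeks_per_season * d.mean())


def build_population_index_table(
    completed: pd.DataFrame,
    surveys: pd.DataFrame,
    weeks_per_season: int = 30,
) -> pd.DataFrame:
    """Assemble the PopulationIndexTable from completed weekly counts.

    ``completed`` holds one row per site x year x week x species with a
    complete ``count`` column (observed or imputed); ``surveys`` supplies
    the observed schedule for the effort covariates, which use observed
    (non-imputed) surveys only.  Produces one row per site x year x
    species over the full grid present in ``completed`` — a species never
    recorded in a site-year gets an explicit zero (or imputed-low) index
    row.
    """
    obs = surveys[surveys["surveyed"]]
    eff = (
        obs.groupby(["site_id", "year"])
        .agg(n_surveys=("week", "size"),
             projected_duration_minutes=("duration_min", "mean"))
        .reset_index()
    )
    eff["projected_duration_minutes"] *= weeks_per_season

    obs_weeks = obs.groupby(["site_id", "year"])["week"].agg(list)

    rows = []
    for (site, year, sp), grp in completed.groupby(
        ["site_id", "year", "species_id"], sort=False
    ):
        grp = grp.sort_values("week")
        rows.append((site, year, sp, trapezoid_index(grp["count"].to_numpy())))
    out = pd.DataFrame(rows, columns=["site_id", "year", "species_id", "index"])
    # list-length is a property of the whole survey (all species recorded),
    # computed from observed (non-imputed) rows only
    ll_all = _site_year_list_length(completed, obs_weeks)
    out = out.merge(ll_all, on=["site_id", "year"], how="left")
    out = out.merge(eff, on=["site_id", "year"], how="left")
    return out


def _site_year_list_length(completed: pd.DataFrame, obs_weeks: pd.Series) -> pd.DataFrame:
    observed = completed[~completed["imputed"]] if "imputed" in completed.columns else completed
    rows = []
    for (site, year), grp in observed.groupby(["site_id", "year"], sort=False):
        weeks = obs_weeks.get((site, year), [])
        if len(weeks) == 0:
            rows.append((site, year, np.nan))
            continue
        rows.append((site, year, mean_list_length(grp, weeks)))
    return pd.DataFrame(rows, columns=["site_id", "year", "mean_list_length"])


def apply_trend_filters(
    indices: pd.DataFrame,
    surveys: pd.DataFrame,
    min_years_site: int = 3,
    min_surveys_year: int = 10,
    min_sites_species: int = 5,
    min_years_species: int = 10,
) -> tuple[pd.DataFrame, dict]:
    """Apply the scheme's inclusion filters for trend estimation.

    Keeps site-years with >= ``min_surveys_year`` surveys at sites having
    >= ``min_years_site`` such qualifying years.  Returns the filtered
    index table and a species -> bool eligibility map for species-level
    trends (present, i.e. index > 0, at >= ``min_sites_species`` retained
    sites and in >= ``min_years_species`` years); every species stays in
    the table for the total-abundance aggregation.
    """
    if indices.empty:
        return indices.copy(), {}
    n_surv = surveys[surveys["surveyed"]].groupby(["site_id", "year"])["week"].size()
    qual_sy = n_surv[n_surv >= min_surveys_year]
    years_per_site = qual_sy.groupby("site_id").size()
    good_sites = set(years_per_site[years_per_site >= min_years_site].index)
    keep = {(s, y) for (s, y) in qual_sy.index if s in good_sites}

    mask = [
        (s, y) in keep
        for s, y in zip(indices["site_id"], indices["year"])
    ]
    filtered = indices[mask].reset_index(drop=True)

    eligibility: dict = {}
    for sp, grp in filtered.groupby("species_id"):
        present = grp[grp["index"] > 0]
        eligibility[sp] = (
            present["site_id"].nunique() >= min_sites_species
            and present["year"].nunique() >= min_years_species
        )
    return filtered, eligibility


def total_abundance_indices(indices: pd.DataFrame) -> pd.DataFrame:
    """Sum species' indices into one total-abundance row per site-year.

    Covariates (list-length, projected duration, survey count) must be
    constant within a site-year — they describe the surveys, not the
    species — and are carried through; conflicting values indicate a
    corrupt table and raise.
    """
    covars = ["mean_list_length", "projected_duration_minutes", "n_surveys"]
    present = [c for c in covars if c in indices.columns]
    for c in present:
        nun = indices.groupby(["site_id", "year"])[c].nunique(dropna=False)
        if (nun > 1).any():
            bad = nun[nun > 1].index[0]
            raise ValueError(f"conflicting {c} within site-year {bad}")
    agg = {"index": "sum", **{c: "first" for c in present}}
    out = indices.groupby(["site_id", "year"], as_index=False).agg(agg)
    out["species_id"] = "total"
    return out


def species_trend_rows(filtered_indices: pd.DataFrame, species_id: str) -> pd.DataFrame:
    """Index rows entering one species' trend model.

    Restricted to site-years at sites where the species was ever recorded;
    site-years there where it went unrecorded keep their explicit zero
    rows.
    """
    sp = filtered_indices[filtered_indices["species_id"] == species_id]
    sites_ever = set(sp.loc[sp["index"] > 0, "site_id"])
    return sp[sp["site_id"].isin(sites_ever)].reset_index(drop=True)
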