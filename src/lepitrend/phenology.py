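"""Degree-day accumulation, regional flight-curve models, and imputation.

Calendar dates are converted to thermal time (growing degree-days, base
5 degrees C, accumulated from January 1) before fitting one penalized
Poisson spline per species to weekly counts.  Modeling phenology in
degree-day time lets a single regional model absorb between-site and
between-year shifts in flight timing; the fitted curve supplies expected
counts for survey weeks that were missed, which downstream trapezoid
integration needs to be complete.

The flight-curve model is a P-spline Poisson regression: cubic B-spline
bases in accumulated degree-days plus low-rank additive smooths of site
latitude and longitude, each with a second-difference coefficient penalty,
and year as an unpenalized categorical term.  Smoothing weights are chosen
by generalized cross-validation on a grid; fitting is plain penalized
Newton/IRLS, which is exact for this log-concave objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = [
    "accumulate_degree_days",
    "degree_day_table",
    "eligible_for_phenology",
    "FlightCurveModel",
    "fit_flight_curve",
    "impute_missing_counts",
    "read_temperature_csv",
]

BASE_TEMP_C = 5.0


def accumulate_degree_days(tmin, tmax, base: float = BASE_TEMP_C) -> np.ndarray:
    """Accumulated growing degree-days from daily tmin/tmax.

    Daily increment is the simple-average estimator
    max(0, (tmin+tmax)/2 - base); the return value is its cumulative sum
    over the input days.
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if tmin.shape != tmax.shape:
        raise ValueError("tmin and tmax must have equal length")
    if np.any(tmax < tmin):
        raise ValueError("tmax < tmin on at least one day")
    inc = np.maximum(0.0, (tmin + tmax) / 2.0 - base)
    return np.cumsum(inc)


def degree_day_table(temperatures: pd.DataFrame, base: float = BASE_TEMP_C) -> pd.DataFrame:
    """Per site-year accumulated GDD for a daily temperature table.

    ``temperatures`` has columns site_id, year, doy, tmin, tmax; rows are
    sorted by doy within each site-year before accumulating from January 1.
    """
    df = temperatures.sort_values(["site_id", "year", "doy"]).copy()
    if np.any(df["tmax"].to_numpy() < df["tmin"].to_numpy()):
        raise ValueError("tmax < tmin in temperature table")
    inc = np.maximum(0.0, (df["tmin"].to_numpy() + df["tmax"].to_numpy()) / 2.0 - base)
    df["gdd"] = pd.Series(inc, index=df.index).groupby(
        [df["site_id"], df["year"]]
    ).cumsum()
    return df[["site_id", "year", "doy", "gdd"]]


def read_temperature_csv(path) -> pd.DataFrame:
    """Read a daily temperature CSV (site_id,year,doy,tmin,tmax)."""
    df = pd.read_csv(path)
    required = {"site_id", "year", "doy", "tmin", "tmax"}
    if not required.issubset(df.columns):
        raise ValueError(f"temperature CSV must have columns {sorted(required)}")
    return df


def eligible_for_phenology(surveys: pd.DataFrame, min_surveys: int = 5) -> pd.DataFrame:
    """Retain site-years with at least ``min_surveys`` surveyed weeks.

    The threshold is inclusive: a site-year with exactly ``min_surveys``
    surveys is kept.  Rows pass through unchanged.
    """
    if surveys.empty:
        return surveys.copy()
    n = surveys[surveys["surveyed"]].groupby(["site_id", "year"])["week"].size()
    keep = set(n[n >= min_surveys].index)
    mask = surveys.set_index(["site_id", "year"]).index.isin(keep)
    return surveys[mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# P-spline machinery

def _bspline_knots(lo: float, hi: float, df: int, degree: int = 3) -> np.ndarray:
    """Open knot vector giving ``df`` cubic B-spline basis functions on [lo, hi]."""
    if hi <= lo:
        hi = lo + 1.0
    n_inner = df - 2
    inner = np.linspace(lo, hi, n_inner)[1:-1]
    return np.concatenate([np.repeat(lo, degree + 1), inner, np.repeat(hi, degree + 1)])


def _bspline_design(x: np.ndarray, knots: np.ndarray, degree: int = 3) -> np.ndarray:
    return BSpline.design_matrix(x, knots, degree).toarray()


def _second_diff_penalty(k: int) -> np.ndarray:
    D = np.diff(np.eye(k), n=2, axis=0)
    return D.T @ D


def _fit_penalized_poisson(y, X, P, maxiter=100, tol=1e-9):
    """Penalized Poisson Newton/IRLS: minimize -loglik + 0.5 b'Pb.

    Returns coefficients, the effective degrees of freedom
    trace((X'WX+P)^-1 X'WX), and the deviance.
    """
    n, k = X.shape
    beta = np.zeros(k)
    beta[0] = np.log(y.mean() + 0.01)

    def obj(b):
        eta = np.clip(X @ b, -30, 30)
        return -float(np.sum(y * eta - np.exp(eta))) + 0.5 * float(b @ P @ b)

    f = obj(beta)
    for _ in range(maxiter):
        eta = np.clip(X @ beta, -30, 30)
        mu = np.exp(eta)
        g = X.T @ (y - mu) - P @ beta
        if np.max(np.abs(g)) < tol * max(1.0, abs(f)):
            break
        XtWX = (X * mu[:, None]).T @ X
        H = XtWX + P
        try:
            delta = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(H, g, rcond=None)[0]
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            fc = obj(cand)
            if fc <= f:
                break
            step *= 0.5
        beta = beta + step * delta
        f = fc
    eta = np.clip(X @ beta, -30, 30)
    mu = np.exp(eta)
    XtWX = (X * mu[:, None]).T @ X
    edf = float(np.trace(np.linalg.solve(XtWX + P, XtWX)))
    with np.errstate(divide="ignore", invalid="ignore"):
        dev_terms = np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu)
    deviance = float(2.0 * np.sum(dev_terms))
    return beta, edf, deviance, mu


@dataclass
class FlightCurveModel:
    """A fitted regional flight-curve model for one species.

    Predictions outside the training degree-day range are clipped to its
    boundary and flagged as extrapolation; years absent from training have
    no dummy level and raise KeyError.
    """

    species_id: str
    coef: np.ndarray = field(repr=False)
    knots_gdd: np.ndarray = field(repr=False)
    knots_lat: np.ndarray | None = field(repr=False)
    knots_lon: np.ndarray | None = field(repr=False)
    year_levels: list
    gdd_range: tuple[float, float]
    lat_range: tuple[float, float]
    lon_range: tuple[float, float]
    alpha: tuple
    edf: float
    deviance_explained: float
    n_train: int
    n_sites: int
    n_years: int

    def _design(self, gdd, lat, lon, year) -> np.ndarray:
        cols = [_year_dummies(year, self.year_levels),
                _bspline_design(gdd, self.knots_gdd)]
        if self.knots_lat is not None:
            cols.append(_bspline_design(lat, self.knots_lat))
            cols.append(_bspline_design(lon, self.knots_lon))
        return np.column_stack(cols)

    def predict(self, gdd, latitude, longitude, year):
        """Expected counts on the response scale plus an extrapolation flag."""
        gdd = np.asarray(gdd, dtype=float)
        lat = np.broadcast_to(np.asarray(latitude, dtype=float), gdd.shape)
        lon = np.broadcast_to(np.asarray(longitude, dtype=float), gdd.shape)
        year = np.broadcast_to(np.asarray(year), gdd.shape)
        missing = set(np.unique(year)) - set(self.year_levels)
        if missing:
            raise KeyError(f"years not in model support: {sorted(missing)}")
        extrapolated = (gdd < self.gdd_range[0]) | (gdd > self.gdd_range[1])
        X = self._design(
            np.clip(gdd, *self.gdd_range),
            np.clip(lat, *self.lat_range),
            np.clip(lon, *self.lon_range),
            year,
        )
        mu = np.exp(np.clip(X @ self.coef, -30, 30))
        return mu, extrapolated


def _year_dummies(year: np.ndarray, levels: list) -> np.ndarray:
    """Intercept plus treatment-coded year dummies (first level reference)."""
    cols = [np.ones(len(year))]
    for lev in levels[1:]:
        cols.append((year == lev).astype(float))
    return np.column_stack(cols)


def fit_flight_curve(
    data: pd.DataFrame,
    species_id: str = "",
    df_gdd: int = 15,
    df_space: int = 5,
    alpha_grid: tuple = (0.1, 1.0, 10.0, 100.0, 1000.0),
    alpha_space: float = 10.0,
    min_nonzero: int = 20,
    min_sites: int = 2,
) -> FlightCurveModel:
    """Fit the regional flight-curve model for one species.

    ``data`` holds one row per surveyed site-week with columns count, gdd,
    latitude, longitude, year (and site_id for the site-count check).  The
    degree-day smoothing weight is chosen by generalized cross-validation
    over ``alpha_grid`` (GCV score n * deviance / (n - edf)^2); the spatial
    smooths carry a fixed moderate penalty.  Refuses to fit with fewer than
    ``min_nonzero`` nonzero-count surveys or fewer than ``min_sites``
    sites among them.
    """
    required = {"count", "gdd", "latitude", "longitude", "year"}
    if not required.issubset(data.columns):
        raise ValueError(f"need columns {sorted(required)}")
    y = data["count"].to_numpy(dtype=float)
    if np.all(y == 0):
        raise ValueError(f"{species_id}: no phenology signal (all counts zero)")
    nz = data[y > 0]
    site_col = "site_id" if "site_id" in data.columns else "latitude"
    if len(nz) < min_nonzero or nz[site_col].nunique() < min_sites:
        raise ValueError(
            f"{species_id}: needs >= {min_nonzero} nonzero-count surveys over "
            f">= {min_sites} sites"
        )

    gdd = data["gdd"].to_numpy(dtype=float)
    lat = data["latitude"].to_numpy(dtype=float)
    lon = data["longitude"].to_numpy(dtype=float)
    year = data["year"].to_numpy()
    year_levels = sorted(pd.unique(data["year"]))

    knots_gdd = _bspline_knots(gdd.min(), gdd.max(), df_gdd)
    spatial = (np.ptp(lat) > 1e-6) and (np.ptp(lon) > 1e-6)
    knots_lat = _bspline_knots(lat.min(), lat.max(), df_space) if spatial else None
    knots_lon = _bspline_knots(lon.min(), lon.max(), df_space) if spatial else None

    n_par = len(year_levels)  # intercept + year dummies
    cols = [_year_dummies(year, year_levels), _bspline_design(gdd, knots_gdd)]
    blocks = [(n_par, df_gdd)]
    if spatial:
        cols.append(_bspline_design(lat, knots_lat))
        cols.append(_bspline_design(lon, knots_lon))
        blocks += [(n_par + df_gdd, df_space), (n_par + df_gdd + df_space, df_space)]
    X = np.column_stack(cols)
    k = X.shape[1]

    def penalty(a_gdd: float) -> np.ndarray:
        P = np.zeros((k, k))
        alphas = [a_gdd] + [alpha_space] * (len(blocks) - 1)
        for (start, df), a in zip(blocks, alphas):
            P[start:start + df, start:start + df] = a * _second_diff_penalty(df)
        # tiny ridge keeps rank-deficient bases solvable
        P += 1e-8 * np.eye(k)
        return P

    n = len(y)
    best = None
    for a_gdd in alpha_grid:
        beta, edf, deviance, mu = _fit_penalized_poisson(y, X, penalty(a_gdd))
        gcv = n * deviance / max(n - edf, 1.0) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, a_gdd, beta, edf, deviance)
    _, a_gdd, beta, edf, deviance = best

    null_dev = _poisson_null_deviance(y)
    return FlightCurveModel(
        species_id=species_id,
        coef=beta,
        knots_gdd=knots_gdd,
        knots_lat=knots_lat,
        knots_lon=knots_lon,
        year_levels=year_levels,
        gdd_range=(float(gdd.min()), float(gdd.max())),
        lat_range=(float(lat.min()), float(lat.max())) if spatial else (0.0, 1.0),
        lon_range=(float(lon.min()), float(lon.max())) if spatial else (0.0, 1.0),
        alpha=(a_gdd, alpha_space),
        edf=edf,
        deviance_explained=float(1.0 - deviance / null_dev) if null_dev > 0 else 0.0,
        n_train=n,
        n_sites=int(data[site_col].nunique()),
        n_years=len(year_levels),
    )


def _poisson_null_deviance(y: np.ndarray) -> float:
    mu = y.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def impute_missing_counts(model: FlightCurveModel, schedule: pd.DataFrame) -> pd.DataFrame:
    """Fill missing survey weeks with flight-curve expected counts.

    ``schedule`` is a site x year x week grid for one species with columns
    gdd, latitude, longitude, year and a ``count`` column that is NaN for
    missing weeks.  Observed counts pass through bit-exact; filled values
    are nonnegative expected counts flagged by a new boolean ``imputed``
    column.  Site-years whose year is outside the model's support stay
    unfilled, with a warning.
    """
    out = schedule.copy()
    out["imputed"] = out["count"].isna()
    if not out["imputed"].any():
        return out
    missing = out[out["imputed"]]
    in_support = missing["year"].isin(model.year_levels)
    if not in_support.all():
        bad = sorted(missing.loc[~in_support, "year"].unique())
        warnings.warn(
            f"{model.species_id}: years {bad} outside model support left unfilled",
            stacklevel=2,
        )
    fillable = missing[in_support]
    if len(fillable):
        mu, extrap = model.predict(
            fillable["gdd"].to_numpy(),
            fillable["latitude"].to_numpy(),
            fillable["longitude"].to_numpy(),
            fillable["year"].to_numpy(),
        )
        out.loc[fillable.index, "count"] = np.maximum(mu, 0.0)
        if "extrapolated" not in out.columns:
            out["extrapolated"] = False
        out.loc[fillable.index, "extrapolated"] = extrap
    return out
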