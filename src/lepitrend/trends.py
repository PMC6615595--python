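"""Abundance trend estimation from population indices.

The trend model is an overdispersed Poisson GLMM on the log link:

    log E[index] = b0 + b_year * year_c + b_ll * listlength_c
                   + log(projected duration)
                   + site + year + observation random intercepts

with year and list-length centered, the projected season-total survey
duration as an offset (making the response a rate of butterflies per
minute), and the observation-level (site x year) random intercept carrying
the extra-Poisson variance.  The year coefficient is the trend; its
annualized form is the geometric-mean rate 100*(exp(b_year)-1) percent per
year.  Species trends are classified positive/negative/stable by the sign
of b_year at a p-value threshold.

Two alternative fits guard against model-choice artifacts: a plain Poisson
GLM (no random effects) and a generalized additive mixed model in which a
penalized spline of year replaces the linear trend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .glmm import ConvergenceError, GLMMResult, fit_poisson_glmm

__all__ = [
    "TrendFit",
    "TrendSummary",
    "SmoothTrendFit",
    "fit_trend_glmm",
    "fit_trend_glm",
    "fit_trend_smooth",
    "annualized_rate",
    "cumulative_change",
    "classify_trend",
    "bootstrap_trend_ci",
    "r2_glmm",
    "summarize_trend",
    "write_trend_table",
]

FIXED_NAMES = ["intercept", "year", "listlength"]


@dataclass
class TrendFit:
    """Fixed effects, variance components, and fit statistics of a trend model."""

    beta0: float
    beta_year: float
    beta_listlength: float
    se: dict[str, float]
    pvalues: dict[str, float]
    sd_site: float
    sd_year: float
    sd_obs: float
    n_groups: dict[str, int]
    loglik: float
    marginal_r2: float
    conditional_r2: float
    n_obs: int
    year_span: tuple[int, int]
    result: GLMMResult | None = field(default=None, repr=False)
    model_frame: pd.DataFrame | None = field(default=None, repr=False)


@dataclass
class TrendSummary:
    annual_rate_percent: float
    cumulative_percent: float
    span_years: int
    ci_low: float | None
    ci_high: float | None
    classification: str


def _model_frame(index_rows: pd.DataFrame) -> pd.DataFrame:
    df = index_rows.copy()
    required = {"site_id", "year", "index", "mean_list_length",
                "projected_duration_minutes"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"index table missing columns {sorted(missing)}")
    if (df["projected_duration_minutes"] <= 0).any():
        raise ValueError("nonpositive projected durations")
    df["y"] = np.round(df["index"]).astype(float)
    df["year_c"] = df["year"] - df["year"].mean()
    df["ll_c"] = df["mean_list_length"] - df["mean_list_length"].mean()
    df["offset"] = np.log(df["projected_duration_minutes"])
    df["site_code"] = pd.factorize(df["site_id"])[0]
    df["year_code"] = pd.factorize(df["year"])[0]
    return df


def fit_trend_glmm(
    index_rows: pd.DataFrame,
    fix_sd: dict[str, float] | None = None,
) -> TrendFit:
    """Fit the overdispersed Poisson GLMM to one species' (or the total) indices.

    Indices are rounded to the nearest integer for the count likelihood.
    ``fix_sd`` can pin random-effect SDs (e.g. all zero, which reduces the
    fit to a plain Poisson GLM).
    """
    df = _model_frame(index_rows)
    if len(df) < 10:
        raise ValueError("need >= 10 index rows")
    if df["year"].nunique() < 2:
        raise ValueError("need >= 2 distinct years")

    X = np.column_stack([np.ones(len(df)), df["year_c"], df["ll_c"]])
    groups = {
        "site": df["site_code"].to_numpy(),
        "year": df["year_code"].to_numpy(),
        "obs": np.arange(len(df)),
    }
    res = fit_poisson_glmm(
        df["y"].to_numpy(), X, groups, offset=df["offset"].to_numpy(),
        exog_names=FIXED_NAMES, fix_sd=fix_sd,
    )
    fit = TrendFit(
        beta0=res.param("intercept"),
        beta_year=res.param("year"),
        beta_listlength=res.param("listlength"),
        se={n: res.se_of(n) for n in FIXED_NAMES},
        pvalues={n: res.pvalue(n) for n in FIXED_NAMES},
        sd_site=res.sd_re["site"],
        sd_year=res.sd_re["year"],
        sd_obs=res.sd_re["obs"],
        n_groups=dict(res.n_groups),
        loglik=res.loglik,
        marginal_r2=np.nan,
        conditional_r2=np.nan,
        n_obs=len(df),
        year_span=(int(df["year"].min()), int(df["year"].max())),
        result=res,
        model_frame=df,
    )
    fit.marginal_r2, fit.conditional_r2 = r2_glmm(fit)
    return fit


def fit_trend_glm(index_rows: pd.DataFrame) -> TrendFit:
    """Poisson GLM alternative: the trend model without any random effects."""
    df = _model_frame(index_rows)
    if len(df) == 0:
        raise ValueError("empty index table")
    X = np.column_stack([np.ones(len(df)), df["year_c"], df["ll_c"]])
    res = sm.GLM(
        df["y"].to_numpy(), X, family=sm.families.Poisson(),
        offset=df["offset"].to_numpy(),
    ).fit()
    se = dict(zip(FIXED_NAMES, np.asarray(res.bse)))
    pv = dict(zip(FIXED_NAMES, np.asarray(res.pvalues)))
    params = np.asarray(res.params)
    return TrendFit(
        beta0=float(params[0]),
        beta_year=float(params[1]),
        beta_listlength=float(params[2]),
        se=se,
        pvalues=pv,
        sd_site=0.0,
        sd_year=0.0,
        sd_obs=0.0,
        n_groups={},
        loglik=float(res.llf),
        marginal_r2=np.nan,
        conditional_r2=np.nan,
        n_obs=len(df),
        year_span=(int(df["year"].min()), int(df["year"].max())),
        result=None,
        model_frame=df,
    )


def annualized_rate(fit: TrendFit, t0: int | None = None, t1: int | None = None) -> float:
    """Annual percent rate of change implied by the fitted trend.

    Under the log-linear model the geometric-mean rate of change of the
    predicted abundance between any two years (list-length at its mean,
    random effects excluded) is constant: 100 * (exp(beta_year) - 1).
    ``t0``/``t1`` are accepted for interface symmetry but do not alter the
    value.
    """
    if t0 is not None and t1 is not None and not t1 > t0:
        raise ValueError("t1 must exceed t0")
    return 100.0 * float(np.expm1(fit.beta_year))


def cumulative_change(fit: TrendFit, span_years: int) -> float:
    """Cumulative percent change over ``span_years`` years of trend."""
    if span_years < 1:
        raise ValueError("span_years must be >= 1")
    return 100.0 * float(np.expm1(fit.beta_year * span_years))


def classify_trend(fit: TrendFit, alpha: float = 0.05) -> str:
    """Classify the trend as positive, negative, or stable at level ``alpha``."""
    p = fit.pvalues["year"]
    if p < alpha and fit.beta_year < 0:
        return "negative"
    if p < alpha and fit.beta_year > 0:
        return "positive"
    return "stable"


def r2_glmm(fit: TrendFit) -> tuple[float, float]:
    """Marginal and conditional R^2 for the mixed trend model.

    Marginal: variance explained by fixed effects over the total latent
    variance (fixed + random + observation-level + distribution-specific);
    conditional adds the random and observation components to the
    numerator.  The distribution-specific variance uses the lognormal
    approximation ln(1 + 1/lambda_bar) for a log-link Poisson, with
    lambda_bar the fixed-effects expected rate per offset unit,
    exp(beta0) — butterflies per minute when the offset is log survey
    minutes (the convention of the mixed-model R^2 implementations).
    """
    df = fit.model_frame
    eta_fixed = fit.beta_year * df["year_c"].to_numpy() + \
        fit.beta_listlength * df["ll_c"].to_numpy()
    var_f = float(np.var(eta_fixed))
    var_site = fit.sd_site ** 2
    var_year = fit.sd_year ** 2
    var_obs = fit.sd_obs ** 2
    lam_bar = float(np.exp(fit.beta0))
    if lam_bar <= 0 or not np.isfinite(lam_bar):
        raise ValueError("degenerate mean rate: R^2 undefined")
    var_dist = float(np.log1p(1.0 / lam_bar))
    total = var_f + var_site + var_year + var_obs + var_dist
    if total <= 0:
        raise ValueError("zero total variance: R^2 undefined")
    marginal = var_f / total
    conditional = (var_f + var_site + var_year + var_obs) / total
    return marginal, conditional


def bootstrap_trend_ci(
    index_rows: pd.DataFrame,
    n_boot: int = 500,
    seed: int = 0,
    level: float = 0.95,
    max_fail_frac: float = 0.2,
) -> dict:
    """Parametric-bootstrap percentile CI for the annual trend rate.

    Responses are simulated from the fitted model (new random effects and
    Poisson noise), the GLMM is refit to each replicate, and percentile
    intervals of beta_year / the annual rate are returned.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    fit = fit_trend_glmm(index_rows)
    rng = np.random.default_rng(seed)
    betas = []
    failures = 0
    for _ in range(n_boot):
        y_star = fit.result.simulate(rng)
        df = index_rows.copy()
        df["index"] = y_star
        try:
            bfit = fit_trend_glmm(df)
        except (ConvergenceError, ValueError, np.linalg.LinAlgError):
            failures += 1
            continue
        betas.append(bfit.beta_year)
    if failures > max_fail_frac * n_boot:
        raise RuntimeError(
            f"{failures}/{n_boot} bootstrap refits failed (> {max_fail_frac:.0%})"
        )
    betas = np.array(betas)
    lo, hi = np.percentile(betas, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return {
        "beta_year": fit.beta_year,
        "beta_ci": (float(lo), float(hi)),
        "annual_rate_ci": (100 * float(np.expm1(lo)), 100 * float(np.expm1(hi))),
        "n_success": len(betas),
        "n_fail": failures,
        "samples": betas,
    }


def summarize_trend(
    fit: TrendFit,
    span_years: int | None = None,
    ci: tuple[float, float] | None = None,
    alpha: float = 0.05,
) -> TrendSummary:
    span = span_years if span_years is not None else fit.year_span[1] - fit.year_span[0]
    return TrendSummary(
        annual_rate_percent=annualized_rate(fit),
        cumulative_percent=cumulative_change(fit, span),
        span_years=span,
        ci_low=None if ci is None else ci[0],
        ci_high=None if ci is None else ci[1],
        classification=classify_trend(fit, alpha=alpha),
    )


# ---------------------------------------------------------------------------
# smooth (GAMM) alternative

@dataclass
class SmoothTrendFit:
    """Nonlinear trend: penalized spline of year in the mixed count model."""

    years: np.ndarray
    relative_abundance: np.ndarray  # predicted, first year = 1
    endpoint_annual_rate_percent: float
    sd_smooth: float
    result: GLMMResult = field(repr=False, default=None)


def _spline_random_basis(year_c: np.ndarray, df_spline: int):
    """Mixed-model reparameterization of a penalized year spline.

    Builds a cubic B-spline basis with a second-difference penalty and
    eigen-rotates it so the penalized directions become iid random effects;
    the penalty null space (constant + linear) is spanned by the model's
    intercept and linear-year fixed effects and is therefore dropped here.
    """
    from scipy.interpolate import BSpline

    lo, hi = year_c.min(), year_c.max()
    n_inner = max(df_spline - 2, 2)
    knots = np.concatenate([
        np.repeat(lo, 4), np.linspace(lo, hi, n_inner)[1:-1], np.repeat(hi, 4)
    ])
    k = len(knots) - 4
    B = BSpline.design_matrix(year_c, knots, 3).toarray()
    D2 = np.diff(np.eye(k), n=2, axis=0)
    S = D2.T @ D2
    vals, vecs = np.linalg.eigh(S)
    keep = vals > 1e-8 * vals.max()
    Z = B @ vecs[:, keep] / np.sqrt(vals[keep])
    return Z, knots


def fit_trend_smooth(index_rows: pd.DataFrame, df_spline: int = 6) -> SmoothTrendFit:
    """GAMM alternative: penalized spline of year replaces the linear trend.

    The spline's smoothness penalty is estimated as a random-effect
    variance by the same Laplace machinery as the main model (site and
    observation random intercepts are retained; the year-factor intercept
    is dropped because the spline plus its wiggliness absorbs interannual
    structure).  Returns per-year relative abundance (first year = 1) and
    the endpoint-to-endpoint annualized rate.
    """
    df = _model_frame(index_rows)
    if df["year"].nunique() < 5:
        raise ValueError("need >= 5 distinct years for a smooth trend")

    year_c = df["year_c"].to_numpy()
    Zs, knots = _spline_random_basis(year_c, df_spline)
    X = np.column_stack([np.ones(len(df)), year_c, df["ll_c"]])
    groups = {
        "smooth": Zs,
        "site": df["site_code"].to_numpy(),
        "obs": np.arange(len(df)),
    }
    res = fit_poisson_glmm(
        df["y"].to_numpy(), X, groups, offset=df["offset"].to_numpy(),
        exog_names=FIXED_NAMES,
    )

    from scipy.interpolate import BSpline

    years = np.sort(df["year"].unique())
    yc = years - df["year"].mean()
    B = BSpline.design_matrix(np.clip(yc, year_c.min(), year_c.max()), knots, 3).toarray()
    D2 = np.diff(np.eye(B.shape[1]), n=2, axis=0)
    S = D2.T @ D2
    vals, vecs = np.linalg.eigh(S)
    keep = vals > 1e-8 * vals.max()
    Zy = B @ vecs[:, keep] / np.sqrt(vals[keep])

    eta = (
        res.param("intercept")
        + res.param("year") * yc
        + res.sd_re["smooth"] * (Zy @ res.u["smooth"])
    )
    rel = np.exp(eta - eta[0])
    span = years[-1] - years[0]
    rate = 100.0 * ((rel[-1] / rel[0]) ** (1.0 / span) - 1.0)
    return SmoothTrendFit(
        years=years,
        relative_abundance=rel,
        endpoint_annual_rate_percent=float(rate),
        sd_smooth=res.sd_re["smooth"],
        result=res,
    )


# ---------------------------------------------------------------------------
# reporting

def write_trend_table(rows: list[dict], path) -> pd.DataFrame:
    """Write the per-species trend table CSV.

    ``rows`` hold per-species dicts (species, totals, sites, years,
    site-years, coefficient, SE, p, classification, annual rate); values
    are written at full precision.
    """
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
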