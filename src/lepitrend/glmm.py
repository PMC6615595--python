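"""Poisson GLMM with crossed random intercepts via the Laplace approximation.

Implements the overdispersed Poisson mixed model used for abundance trends:
log-link Poisson counts with fixed effects, an offset, and independent
Gaussian random intercepts for each grouping factor — including an
observation-level factor (one level per row), which is the standard
device for extra-Poisson variance in a count GLMM.

Estimation follows the usual two-level scheme: for candidate random-effect
SDs theta, penalized IRLS (Newton on the joint log-density of data and
scaled random effects) profiles out the fixed effects and random modes;
the Laplace-approximate deviance

    -2 log L(theta) = -2 log p(y | beta*, u*) + ||u*||^2
                      + log det(Zs' W Zs + I)

is then minimized over theta >= 0 with a bounded quasi-Newton optimizer.
Wald standard errors for fixed effects come from the fixed-effect block of
the inverse joint Hessian at the optimum (conditional on theta), matching
common mixed-model practice.

A grouping factor may also be given as a dense design matrix with iid
N(0, sd^2) coefficients, which is how the mixed-model representation of a
penalized spline plugs into the same machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, sparse
from scipy.sparse.linalg import splu
from scipy.special import gammaln
from scipy.stats import norm

__all__ = ["ConvergenceError", "GLMMResult", "fit_poisson_glmm"]


class ConvergenceError(RuntimeError):
    """Raised when the penalized IRLS inner loop fails to converge."""

    def __init__(self, grad_norm: float, n_iter: int):
        self.grad_norm = grad_norm
        self.n_iter = n_iter
        super().__init__(
            f"GLMM did not converge: gradient inf-norm {grad_norm:.3g} "
            f"after {n_iter} iterations"
        )


@dataclass
class GLMMResult:
    """Fitted Poisson GLMM."""

    params: np.ndarray
    se: np.ndarray
    exog_names: list[str]
    sd_re: dict[str, float]
    n_groups: dict[str, int]
    loglik: float
    deviance: float
    u: dict[str, np.ndarray]
    fitted: np.ndarray
    converged: bool
    n_iter_outer: int
    singular: bool
    # retained for simulation / refitting
    _y: np.ndarray = field(repr=False, default=None)
    _X: np.ndarray = field(repr=False, default=None)
    _offset: np.ndarray = field(repr=False, default=None)
    _groups: dict = field(repr=False, default=None)

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.zvalues))

    def param(self, name: str) -> float:
        return float(self.params[self.exog_names.index(name)])

    def se_of(self, name: str) -> float:
        return float(self.se[self.exog_names.index(name)])

    def pvalue(self, name: str) -> float:
        return float(self.pvalues[self.exog_names.index(name)])

    def simulate(self, rng: np.random.Generator) -> np.ndarray:
        """Draw a response vector from the fitted model (new random effects)."""
        eta = self._X @ self.params + self._offset
        for name, Zg in _group_designs(self._groups).items():
            q = Zg.shape[1]
            eta = eta + self.sd_re[name] * (Zg @ rng.normal(0.0, 1.0, q))
        return rng.poisson(np.exp(np.clip(eta, -30.0, 30.0))).astype(float)


def _group_designs(groups: dict) -> dict:
    out = {}
    for name, g in groups.items():
        g = np.asarray(g)
        if g.ndim == 1:
            codes = g.astype(int)
            q = codes.max() + 1
            Z = sparse.csr_matrix(
                (np.ones(len(codes)), (np.arange(len(codes)), codes)),
                shape=(len(codes), q),
            )
        else:
            Z = sparse.csr_matrix(g.astype(float))
        out[name] = Z
    return out


def _poisson_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    mu = np.exp(np.clip(eta, -700, 700))
    return float(np.sum(y * eta - mu - gammaln(y + 1.0)))


def fit_poisson_glmm(
    y,
    X,
    groups: dict,
    offset=None,
    exog_names: list[str] | None = None,
    fix_sd: dict[str, float] | None = None,
    start_sd: float = 0.3,
    inner_tol: float = 1e-7,
    inner_maxiter: int = 200,
    outer_maxiter: int = 500,
    singular_tol: float = 1e-4,
) -> GLMMResult:
    """Fit a log-link Poisson GLMM with crossed random intercepts.

    Parameters
    ----------
    y : nonnegative counts, shape (n,)
    X : fixed-effect design, shape (n, p)
    groups : mapping of factor name to either integer level codes
        (shape (n,), levels 0..q-1) or a dense random-effect design matrix.
    offset : optional log-scale offset, shape (n,)
    fix_sd : SDs to hold fixed (e.g. ``{"site": 0.0}``); factors not listed
        have their SD estimated by Laplace ML.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y and X row counts differ")
    if np.any(y < 0):
        raise ValueError("negative counts")
    offset = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    exog_names = exog_names or [f"x{j}" for j in range(p)]
    fix_sd = dict(fix_sd or {})

    designs = _group_designs(groups)
    names = list(designs)
    q_sizes = [designs[g].shape[1] for g in names]
    q = int(np.sum(q_sizes))
    Z_all = sparse.hstack([sparse.csr_matrix(X)] + [designs[g] for g in names],
                          format="csc")
    pen = np.concatenate([np.zeros(p), np.ones(q)])
    P = sparse.diags(pen)
    u_slices = {}
    ofs = p
    for g, qg in zip(names, q_sizes):
        u_slices[g] = slice(ofs, ofs + qg)
        ofs += qg

    free = [g for g in names if g not in fix_sd]
    state = {"coef": np.zeros(p + q), "inner_iters": 0, "grad_norm": np.inf}

    def theta_vector(x_free: np.ndarray) -> np.ndarray:
        th = np.empty(len(names))
        j = 0
        for i, g in enumerate(names):
            if g in fix_sd:
                th[i] = fix_sd[g]
            else:
                th[i] = x_free[j]
                j += 1
        return th

    def scaled_design(theta: np.ndarray):
        s = np.concatenate(
            [np.ones(p)] + [np.full(qg, th) for th, qg in zip(theta, q_sizes)]
        )
        return Z_all @ sparse.diags(s)

    def pirls(theta: np.ndarray, coef: np.ndarray):
        M = scaled_design(theta)
        Mt = M.T.tocsr()

        def obj(c):
            eta = offset + M @ c
            return -float(np.sum(y * eta - np.exp(np.clip(eta, -700, 700)))) \
                + 0.5 * float(np.sum(c[p:] ** 2))

        f = obj(coef)
        grad_norm = np.inf
        lu = None
        for it in range(inner_maxiter):
            eta = offset + M @ coef
            mu = np.exp(np.clip(eta, -30.0, 30.0))
            grad = Mt @ (y - mu) - pen * coef
            grad_norm = float(np.max(np.abs(grad)))
            if grad_norm < inner_tol * max(1.0, abs(f)) or grad_norm < 1e-9:
                break
            H = (Mt @ sparse.diags(mu) @ M) + P
            try:
                lu = splu(H.tocsc())
            except RuntimeError as err:  # singular working Hessian
                raise ConvergenceError(grad_norm, it) from err
            delta = lu.solve(grad)
            # step halving on the penalized objective
            step = 1.0
            for _ in range(30):
                cand = coef + step * delta
                fc = obj(cand)
                if fc <= f + 1e-12:
                    break
                step *= 0.5
            coef = coef + step * delta
            f = obj(coef)
        eta = offset + M @ coef
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        return coef, mu, M, grad_norm, it + 1

    def laplace_deviance(theta: np.ndarray):
        coef, mu, M, grad_norm, iters = pirls(theta, state["coef"])
        state["coef"] = coef
        state["grad_norm"] = grad_norm
        state["inner_iters"] = iters
        Mz = M[:, p:].tocsc()
        Huu = ((Mz.T @ sparse.diags(mu) @ Mz) + sparse.identity(q)).tocsc()
        lu = splu(Huu)
        logdet = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        eta = offset + M @ coef
        dev = -2.0 * _poisson_loglik(y, eta) + float(np.sum(coef[p:] ** 2)) + logdet
        return dev, coef, mu, M

    n_outer = 0
    if free:
        x0 = np.full(len(free), start_sd)

        def fun(x):
            try:
                return laplace_deviance(theta_vector(x))[0]
            except ConvergenceError:
                return 1e12  # steer the optimizer away from degenerate theta

        opt = optimize.minimize(
            fun,
            x0,
            method="L-BFGS-B",
            bounds=[(0.0, 10.0)] * len(free),
            options={"maxiter": outer_maxiter, "eps": 1e-4, "ftol": 1e-10},
        )
        theta = theta_vector(np.asarray(opt.x))
        n_outer = int(opt.nit)
    else:
        theta = theta_vector(np.empty(0))

    dev, coef, mu, M = laplace_deviance(theta)
    if state["grad_norm"] > 1e-2 * max(1.0, dev):
        raise ConvergenceError(state["grad_norm"], state["inner_iters"])

    # Wald covariance of fixed effects: beta block of the inverse joint Hessian
    Mt = M.T.tocsr()
    H = (Mt @ sparse.diags(mu) @ M) + P
    lu = splu(H.tocsc())
    rhs = np.zeros((p + q, p))
    rhs[:p, :p] = np.eye(p)
    cov = lu.solve(rhs)[:p, :p]
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    sd_re = {g: float(theta[i]) for i, g in enumerate(names)}
    singular = any(sd_re[g] < singular_tol for g in free)
    if singular:
        warnings.warn(
            "singular random-effect fit: SD at the zero boundary for "
            + ", ".join(g for g in free if sd_re[g] < singular_tol),
            stacklevel=2,
        )
        for g in free:
            if sd_re[g] < singular_tol:
                sd_re[g] = 0.0

    u = {g: coef[u_slices[g]].copy() for g in names}
    return GLMMResult(
        params=coef[:p].copy(),
        se=se,
        exog_names=list(exog_names),
        sd_re=sd_re,
        n_groups={g: designs[g].shape[1] for g in names},
        loglik=-dev / 2.0,
        deviance=dev,
        u=u,
        fitted=mu,
        converged=True,
        n_iter_outer=n_outer,
        singular=singular,
        _y=y,
        _X=X,
        _offset=offset,
        _groups=dict(groups),
    )
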