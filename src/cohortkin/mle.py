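"""Maximum-likelihood fitting of the Weibull survival model.

For a complete (uncensored) sample of ages at death x_1..x_n the
log-likelihood expands to

    logL(a, b) = n log b - n b log a + (b - 1) sum(log x) - sum((x/a)^b),

whose analytic gradient (score) and Hessian are:

    dL/da   = -n b / a + (b / a) S_b
    dL/db   =  n / b - n log a + sum(log x) - T_b
    d2L/da2 =  n b / a^2 - b (b + 1) / a^2 * S_b
    d2L/dadb = -n / a + (1 / a) S_b + (b / a) T_b
    d2L/db2 = -n / b^2 - U_b

with S_b = sum((x/a)^b), T_b = sum((x/a)^b log(x/a)),
U_b = sum((x/a)^b log(x/a)^2).

The Newton-Raphson recurrence theta_{k+1} = theta_k - H^{-1} g is run on the
log-parameter scale (log a, log b) so every iterate stays positive, with the
chain rule applied to the score and Hessian.  Steps that fail to increase
the log-likelihood are halved (up to 30 times), and a steepest-ascent
fallback handles iterates where the Hessian is not negative definite.
Standard errors come from the observed information (inverse negative
Hessian) at the optimum, reported on the original (alpha, beta) scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lifetable import CohortData, build_life_table
from .weibull import WeibullParams

__all__ = [
    "FitResult",
    "SurfaceGrid",
    "log_likelihood",
    "negative_log_likelihood",
    "score",
    "hessian",
    "initialize_params",
    "newton_raphson_fit",
    "standard_errors",
    "profile_nll",
    "nll_surface",
    "SingularHessianError",
]


class SingularHessianError(RuntimeError):
    """Raised when a Newton step cannot be computed; carries the trace."""

    def __init__(self, message: str, trace):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class FitResult:
    params: WeibullParams
    loglik: float
    score_at_opt: np.ndarray
    hessian_at_opt: np.ndarray
    std_errors: tuple[float, float]
    n_iter: int
    converged: bool
    trace: list  # (WeibullParams, gradient max-norm) per iteration
    n_obs: int
    init_method: str = "loglog-regression"

    def to_dict(self) -> dict:
        return {
            "alpha": self.params.alpha,
            "beta": self.params.beta,
            "se_alpha": self.std_errors[0],
            "se_beta": self.std_errors[1],
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "init_method": self.init_method,
        }


@dataclass(frozen=True)
class SurfaceGrid:
    """Negative log-likelihood evaluated on an (alpha, beta) lattice."""

    alpha_grid: np.ndarray
    beta_grid: np.ndarray
    nll: np.ndarray  # shape (len(alpha_grid), len(beta_grid))
    argmin: tuple[int, int] = field(init=False)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.nll)):
            raise ValueError("negative log-likelihood not finite on the grid")
        ij = np.unravel_index(int(np.argmin(self.nll)), self.nll.shape)
        object.__setattr__(self, "argmin", (int(ij[0]), int(ij[1])))

    @property
    def argmin_params(self) -> WeibullParams:
        i, j = self.argmin
        return WeibullParams(float(self.alpha_grid[i]), float(self.beta_grid[j]))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.nll,
            index=pd.Index(self.alpha_grid, name="alpha"),
            columns=pd.Index(self.beta_grid, name="beta"),
        )


def _ages(cohort) -> np.ndarray:
    x = cohort.ages_at_death if isinstance(cohort, CohortData) else np.asarray(cohort, float)
    if x.size == 0:
        raise ValueError("empty sample")
    if np.any(x <= 0):
        raise ValueError("log-likelihood undefined: every age must be > 0")
    return x


def log_likelihood(params: WeibullParams, cohort) -> float:
    x = _ages(cohort)
    a, b = params.alpha, params.beta
    n = x.size
    z = x / a
    return float(
        n * np.log(b) - n * b * np.log(a) + (b - 1.0) * np.sum(np.log(x)) - np.sum(z**b)
    )


def negative_log_likelihood(params: WeibullParams, cohort) -> float:
    return -log_likelihood(params, cohort)


def score(params: WeibullParams, cohort) -> np.ndarray:
    """Gradient of the log-likelihood in (alpha, beta)."""
    x = _ages(cohort)
    a, b = params.alpha, params.beta
    n = x.size
    logz = np.log(x) - np.log(a)
    zb = np.exp(b * logz)
    s_b = zb.sum()
    t_b = (zb * logz).sum()
    d_a = -n * b / a + (b / a) * s_b
    d_b = n / b - n * np.log(a) + np.sum(np.log(x)) - t_b
    return np.array([d_a, d_b])


def hessian(params: WeibullParams, cohort) -> np.ndarray:
    """Matrix of second partials of the log-likelihood; symmetric."""
    x = _ages(cohort)
    a, b = params.alpha, params.beta
    n = x.size
    logz = np.log(x) - np.log(a)
    zb = np.exp(b * logz)
    s_b = zb.sum()
    t_b = (zb * logz).sum()
    u_b = (zb * logz * logz).sum()
    d_aa = n * b / a**2 - b * (b + 1.0) / a**2 * s_b
    d_ab = -n / a + s_b / a + (b / a) * t_b
    d_bb = -n / b**2 - u_b
    return np.array([[d_aa, d_ab], [d_ab, d_bb]])


def initialize_params(cohort) -> tuple[WeibullParams, str]:
    """Starting values for the Newton iteration.

    The cumulative hazard of a Weibull is (t/alpha)^beta, so
    log(-log lx) regressed on log age has slope beta and intercept
    -beta log alpha; the least-squares line over the interior life-table
    points (0 < lx < 1) seeds both parameters.  With fewer than two usable
    points a method-of-moments seed is used instead (shape from the sample
    coefficient of variation, scale from the mean).
    """
    x = _ages(cohort)
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct ages to fit")
    label = cohort.label if isinstance(cohort, CohortData) else "sample"
    cd = cohort if isinstance(cohort, CohortData) else CohortData(x, label)
    # bin on ~30 intervals so small cohorts still yield interior points
    table = build_life_table(cd, bin_width=float(x.max()) / 30.0)
    mask = (table.lx > 0) & (table.lx < 1) & (table.ages > 0)
    if mask.sum() >= 2:
        lx = table.lx[mask]
        t = table.ages[mask]
        yy = np.log(-np.log(lx))
        tt = np.log(t)
        slope, intercept = np.polyfit(tt, yy, 1)
        if slope > 0:
            beta0 = float(slope)
            alpha0 = float(np.exp(-intercept / slope))
            return WeibullParams(alpha0, beta0), "loglog-regression"
    # moment seed: CV of a Weibull is decreasing in beta; beta ~ CV^-1.086
    # (Justus' reliability-engineering approximation)
    cv = x.std(ddof=1) / x.mean()
    beta0 = float(np.clip(cv ** (-1.086), 0.05, 100.0))
    from .weibull import _gamma

    alpha0 = float(x.mean() / _gamma(1.0 + 1.0 / beta0))
    return WeibullParams(alpha0, beta0), "method-of-moments"


def _log_scale_derivs(params: WeibullParams, x: np.ndarray):
    """Score and Hessian with respect to (log alpha, log beta)."""
    g = score(params, x)
    h = hessian(params, x)
    a, b = params.alpha, params.beta
    g_log = np.array([a * g[0], b * g[1]])
    h_log = np.array(
        [
            [a * a * h[0, 0] + a * g[0], a * b * h[0, 1]],
            [a * b * h[0, 1], b * b * h[1, 1] + b * g[1]],
        ]
    )
    return g_log, h_log


def newton_raphson_fit(
    cohort,
    init: WeibullParams | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> FitResult:
    """Fit (alpha, beta) by safeguarded Newton-Raphson on the score.

    Convergence: gradient max-norm < ``tol`` on the log-parameter scale, or
    relative parameter change < 1e-10.  Exceeding ``max_iter`` returns an
    unconverged :class:`FitResult`; a step that cannot be computed raises
    :class:`SingularHessianError` with the trace attached.
    """
    x = _ages(cohort)
    if np.unique(x).size < 2:
        raise ValueError("degenerate sample: need >= 2 distinct ages")
    if init is None:
        init, init_method = initialize_params(cohort)
    else:
        init_method = "user"
    theta = np.log([init.alpha, init.beta])
    ll = log_likelihood(init, x)
    trace: list[tuple[WeibullParams, float]] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        p = WeibullParams(*np.exp(theta))
        g, h = _log_scale_derivs(p, x)
        gnorm = float(np.max(np.abs(g)))
        trace.append((p, gnorm))
        if gnorm < tol:
            converged = True
            break
        # Newton direction; steepest ascent if H is not usable
        neg_def = np.all(np.linalg.eigvalsh(h) < 0)
        if neg_def:
            try:
                step = -np.linalg.solve(h, g)
            except np.linalg.LinAlgError:
                raise SingularHessianError("singular Hessian in Newton step", trace)
            if not np.all(np.isfinite(step)):
                raise SingularHessianError("non-finite Newton step", trace)
        else:
            step = g / max(np.max(np.abs(g)), 1.0)
        # halve until the log-likelihood increases and stays finite
        lam, new_ll, new_theta = 1.0, -np.inf, theta
        for _ in range(30):
            cand = theta + lam * step
            if np.all(np.abs(cand) < 700):
                cand_ll = log_likelihood(WeibullParams(*np.exp(cand)), x)
                if np.isfinite(cand_ll) and cand_ll > ll - 1e-13:
                    new_ll, new_theta = cand_ll, cand
                    break
            lam *= 0.5
        else:
            converged = gnorm < 1e2 * tol
            break
        if np.max(np.abs(new_theta - theta)) < 1e-10 * (1 + np.max(np.abs(theta))):
            theta, ll = new_theta, new_ll
            p = WeibullParams(*np.exp(theta))
            g, _ = _log_scale_derivs(p, x)
            trace.append((p, float(np.max(np.abs(g)))))
            converged = True
            break
        theta, ll = new_theta, new_ll
    params = WeibullParams(*np.exp(theta))
    g = score(params, x)
    h = hessian(params, x)
    se = _std_errors_from_hessian(h)
    return FitResult(
        params=params,
        loglik=log_likelihood(params, x),
        score_at_opt=g,
        hessian_at_opt=h,
        std_errors=se,
        n_iter=n_iter,
        converged=converged,
        trace=trace,
        n_obs=x.size,
        init_method=init_method,
    )


def _std_errors_from_hessian(h: np.ndarray) -> tuple[float, float]:
    info = -h
    try:
        cov = np.linalg.inv(info)
        d = np.diag(cov)
        if np.all(d > 0):
            return (float(np.sqrt(d[0])), float(np.sqrt(d[1])))
    except np.linalg.LinAlgError:
        pass
    return (float("nan"), float("nan"))


def standard_errors(fit: FitResult) -> tuple[float, float]:
    """sqrt of the diagonal of the inverse observed information at the MLE."""
    if not fit.converged:
        raise ValueError("standard errors require a converged fit")
    info = -fit.hessian_at_opt
    eig = np.linalg.eigvalsh(info)
    if np.any(eig <= 0):
        raise ValueError(
            "observed information is not positive definite; the optimum is "
            "not a proper maximum"
        )
    d = np.diag(np.linalg.inv(info))
    return (float(np.sqrt(d[0])), float(np.sqrt(d[1])))


def _nll_grid(x: np.ndarray, alphas: np.ndarray, betas: np.ndarray) -> np.ndarray:
    """Vectorized negative log-likelihood over the (alpha, beta) lattice."""
    n = x.size
    logx = np.log(x)
    logx_sum = logx.sum()
    nll = np.empty((alphas.size, betas.size))
    for i, a in enumerate(alphas):  # row at a time keeps memory at n * nb
        logz = logx - np.log(a)
        s = np.exp(logz[:, None] * betas[None, :]).sum(axis=0)
        ll = n * np.log(betas) - n * betas * np.log(a) + (betas - 1.0) * logx_sum - s
        nll[i] = -ll
    return nll


def nll_surface(cohort, alpha_grid, beta_grid) -> SurfaceGrid:
    """Negative log-likelihood on a lattice, with the argmin recorded.

    The grid search is the optimizer-free view of the same objective the
    Newton iteration minimizes, useful both for visualisation and as an
    independent check on the fitted optimum.
    """
    x = _ages(cohort)
    alphas = np.asarray(alpha_grid, float)
    betas = np.asarray(beta_grid, float)
    for name, g in (("alpha_grid", alphas), ("beta_grid", betas)):
        if np.any(g <= 0) or (g.size > 1 and np.any(np.diff(g) <= 0)):
            raise ValueError(f"{name} must be positive and strictly increasing")
    nll = _nll_grid(x, alphas, betas)
    return SurfaceGrid(alphas, betas, nll)


def profile_nll(cohort, fixed_alpha: float, beta_grid) -> np.ndarray:
    """Negative log-likelihood along a beta grid at fixed alpha."""
    if fixed_alpha <= 0:
        raise ValueError("fixed_alpha must be positive")
    x = _ages(cohort)
    betas = np.asarray(beta_grid, float)
    if np.any(betas <= 0) or (betas.size > 1 and np.any(np.diff(betas) <= 0)):
        raise ValueError("beta_grid must be positive and strictly increasing")
    return _nll_grid(x, np.array([fixed_alpha]), betas)[0]
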