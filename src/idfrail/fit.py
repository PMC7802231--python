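"""Maximum-likelihood fitting for the shared-frailty illness-death model.

The likelihood is maximized by a quasi-Newton optimizer (L-BFGS-B) over the
packed parameter vector.  Standard errors come from the inverse of the
observed information matrix, computed by central finite differences of the
log-likelihood at the optimum.

Starting values follow a two-stage scheme:

* **Weibull baselines** — each transition is first fit as a univariate
  left-truncated Weibull proportional-hazards model on its own risk window
  (transitions 1 and 2 on the main clock with delayed entry; transition 3
  among subjects with the nonterminal event, on the gap clock for the
  clock-reset model or with delayed entry at the illness time for the
  Markov model).
* **B-spline baselines** — univariate Cox fits per transition give the
  regression starts and a Breslow step cumulative baseline hazard, which is
  linearly interpolated on a uniform grid, differentiated, smoothed by
  loess, floored and logged; the control points minimizing the least-squares
  distance between the smoothed log hazard and the spline basis are the
  baseline starts.

The frailty variance is initialized at ``theta = 0.5``, optimized on the log
scale with a floor at ``log theta = -15`` (estimates at the floor are
reported as "frailty variance ~ 0").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from .hazards import BSplineHazardParams, bspline_basis
from .likelihood import (
    BaselineSpec,
    LikelihoodEvaluator,
    ModelSpec,
    ParameterVector,
)

__all__ = [
    "FitResult",
    "weibull_start",
    "cox_breslow_start",
    "smooth_log_hazard",
    "bspline_start",
    "fit_model",
    "wald_table",
    "wald_joint_test",
    "select_bspline_model",
    "baseline_hazard_function",
]

LOG_THETA_FLOOR = -15.0


@dataclass
class FitResult:
    """MLE, covariance (estimation scale), log-likelihood and diagnostics."""

    phi: np.ndarray
    parameter_names: list[str]
    covariance: Optional[np.ndarray]
    loglik: float
    converged: bool
    spec: ModelSpec  # knots resolved
    n: int
    n_iter: int = 0
    grad_norm: float = np.nan
    message: str = ""
    start: Optional[np.ndarray] = None

    @property
    def params(self) -> ParameterVector:
        return ParameterVector.from_array(self.phi, self.spec)

    @property
    def se(self) -> Optional[np.ndarray]:
        if self.covariance is None:
            return None
        d = np.diag(self.covariance)
        return np.sqrt(np.maximum(d, 0.0))

    @property
    def theta_at_floor(self) -> bool:
        """True when the frailty variance hit its lower boundary (~0)."""
        return (
            self.spec.frailty
            and self.phi[-1] <= LOG_THETA_FLOOR + 1e-6
        )


# ---------------------------------------------------------------------------
# transition-specific risk windows


def _transition_window(data: pd.DataFrame, k: int, spec: ModelSpec):
    """(entry, exit, event, X) arrays for the transition-k univariate model."""
    s = spec.time_scale
    L = data["L"].to_numpy(float) / s
    y1 = data["y1"].to_numpy(float) / s
    y2 = data["y2"].to_numpy(float) / s
    d1 = data["delta1"].to_numpy(int)
    d2 = data["delta2"].to_numpy(int)
    cov = list(spec.covariates[k - 1])
    X = data[cov].to_numpy(float) if cov else np.empty((len(L), 0))
    if k == 1:
        return L, y1, d1, X
    if k == 2:
        return L, y1, (1 - d1) * d2, X
    m = d1 == 1
    if spec.lambda3_clock == "semi_markov":
        entry = np.zeros(m.sum())
        exit_ = (y2 - y1)[m]
    else:
        entry = y1[m]
        exit_ = y2[m]
    return entry, exit_, d2[m], X[m]


def weibull_start(data: pd.DataFrame, k: int, spec: ModelSpec):
    """Univariate left-truncated Weibull PH MLE for transition ``k``.

    Returns ``(xi_k, beta_k)`` with ``xi_k = (log alpha, log kappa)``.
    """
    entry, exit_, event, X = _transition_window(data, k, spec)
    keep = exit_ > entry
    entry, exit_, event, X = entry[keep], exit_[keep], event[keep], X[keep]
    if event.sum() == 0:
        raise ValueError(f"no events observed for transition {k}")
    ev = event.astype(bool)
    with np.errstate(divide="ignore"):
        log_exit = np.log(exit_)
        log_entry = np.where(entry > 0, np.log(entry), -np.inf)

    def negll(par):
        la, lk = par[0], par[1]
        beta = par[2:]
        alpha = np.exp(la)
        lp = X @ beta if beta.size else 0.0
        with np.errstate(over="ignore"):
            expo = np.exp(lk + lp) * (
                np.exp(alpha * log_exit) - np.exp(alpha * log_entry)
            )
            ll = np.sum(la + lk + (alpha - 1.0) * log_exit[ev] + (lp[ev] if beta.size else 0.0)) - np.sum(expo)
        return -ll if np.isfinite(ll) else 1e10

    # exponential-model start: alpha=1, kappa = events / total exposure
    exposure = np.sum(exit_ - entry)
    x0 = np.r_[0.0, np.log(event.sum() / exposure), np.zeros(X.shape[1])]
    res = minimize(negll, x0, method="L-BFGS-B")
    if not res.success:
        warnings.warn(f"Weibull start for transition {k}: {res.message}")
    return res.x[:2].copy(), res.x[2:].copy()


def _breslow(entry, exit_, event, X, beta):
    """Breslow cumulative baseline hazard under delayed entry.

    At each distinct event time t: increment = (#events at t) /
    sum of exp(x'beta) over subjects at risk (entry < t <= exit).
    """
    ev_times = np.unique(exit_[event.astype(bool)])
    risk_score = np.exp(X @ beta) if beta.size else np.ones(len(exit_))
    incr = np.empty(len(ev_times))
    for j, t in enumerate(ev_times):
        at_risk = (entry < t) & (exit_ >= t)
        d = np.sum(event.astype(bool) & (exit_ == t))
        incr[j] = d / risk_score[at_risk].sum()
    return ev_times, np.cumsum(incr)


def cox_breslow_start(data: pd.DataFrame, k: int, spec: ModelSpec):
    """Cox partial-likelihood fit + Breslow baseline for transition ``k``.

    Returns ``(beta_k, (event_times, cumulative_baseline_hazard))``.
    Delayed entry is honored for transitions 1 and 2; transition 3 is fit
    only among subjects with the nonterminal event, on the model's clock.
    """
    entry, exit_, event, X = _transition_window(data, k, spec)
    keep = exit_ > entry
    entry, exit_, event, X = entry[keep], exit_[keep], event[keep], X[keep]
    if event.sum() == 0:
        raise ValueError(f"no events observed for transition {k}")
    p = X.shape[1]
    if p == 0:
        beta = np.empty(0)
    else:
        from lifelines import CoxPHFitter

        df = pd.DataFrame(X, columns=[f"x{j}" for j in range(p)])
        df["entry"] = entry
        df["time"] = exit_
        df["event"] = event
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event", entry_col="entry")
        beta = cph.params_.to_numpy()
    times, cumhaz = _breslow(entry, exit_, event, X, beta)
    return beta, (times, cumhaz)


def smooth_log_hazard(
    times: np.ndarray,
    cumhaz: np.ndarray,
    grid_size: int = 101,
    span: float = 0.75,
    floor: float = 1e-8,
):
    """Smooth log-hazard curve from a step cumulative hazard.

    Linear interpolation of the cumulative hazard on a uniform grid over the
    event-time range, central-difference differentiation, loess smoothing of
    the hazard, flooring at a small positive value, then log.  Returns
    ``(grid, log_hazard)``.
    """
    times = np.asarray(times, float)
    cumhaz = np.asarray(cumhaz, float)
    if len(np.unique(times)) < 5:
        raise ValueError(
            "fewer than 5 distinct event times; use Weibull starting values"
        )
    grid = np.linspace(times.min(), times.max(), grid_size)
    H = np.interp(grid, times, cumhaz)
    haz = np.gradient(H, grid)
    from statsmodels.nonparametric.smoothers_lowess import lowess

    smooth = lowess(haz, grid, frac=span, return_sorted=False)
    return grid, np.log(np.maximum(smooth, floor))


def bspline_start(
    grid: np.ndarray, log_hazard: np.ndarray, baseline: BaselineSpec
) -> np.ndarray:
    """Least-squares control points fitting a log-hazard curve.

    Ordinary least squares of the spline basis (evaluated on ``grid``)
    against ``log_hazard``.
    """
    if not baseline.knots_resolved or baseline.family != "bspline":
        raise ValueError("baseline must be a bspline spec with resolved knots")
    p = BSplineHazardParams(
        baseline.degree,
        baseline.boundary_knots,
        baseline.interior_knots,
        np.zeros(baseline.n_params),
    )
    D = bspline_basis(np.asarray(grid, float), baseline.degree, p)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError(
            "rank-deficient spline basis on this grid; "
            "use fewer knots or a lower degree"
        )
    eta, *_ = np.linalg.lstsq(D, np.asarray(log_hazard, float), rcond=None)
    return eta


# ---------------------------------------------------------------------------
# main fit


def _default_start(evaluator: LikelihoodEvaluator, data: pd.DataFrame) -> np.ndarray:
    spec = evaluator.spec
    xi_parts, beta_parts = [], []
    for k, b in enumerate(spec.baselines, start=1):
        if b.family == "weibull":
            xi, beta = weibull_start(data, k, spec)
        else:
            beta, (times, cumhaz) = cox_breslow_start(data, k, spec)
            try:
                grid, logh = smooth_log_hazard(times, cumhaz)
                xi = bspline_start(grid, logh, spec.baselines[k - 1])
            except ValueError:
                # sparse events: fall back to a constant log hazard
                rate = np.log(max(cumhaz[-1] / max(times[-1], 1e-12), 1e-8))
                xi = np.full(b.n_params, rate)
        xi_parts.append(xi)
        beta_parts.append(beta)
    parts = xi_parts + beta_parts
    if spec.frailty:
        parts.append(np.array([np.log(0.5)]))
    return np.concatenate([np.atleast_1d(p) for p in parts])


def _numerical_hessian(f: Callable, x: np.ndarray) -> np.ndarray:
    """Central-difference Hessian with per-parameter steps."""
    p = len(x)
    h = np.maximum(1e-4, 1e-4 * np.abs(x))
    H = np.empty((p, p))
    f0 = f(x)
    fp = np.empty(p)
    fm = np.empty(p)
    for i in range(p):
        e = np.zeros(p)
        e[i] = h[i]
        fp[i] = f(x + e)
        fm[i] = f(x - e)
        H[i, i] = (fp[i] + fm[i] - 2.0 * f0) / h[i] ** 2
    for i in range(p):
        for j in range(i + 1, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = h[i]
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _numerical_gradient(f: Callable, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
    g = np.empty(len(x))
    for i in range(len(x)):
        e = np.zeros(len(x))
        e[i] = h * max(1.0, abs(x[i]))
        g[i] = (f(x + e) - f(x - e)) / (2.0 * e[i])
    return g


def fit_model(
    data: pd.DataFrame,
    spec: ModelSpec,
    start: Optional[np.ndarray] = None,
    max_iter: int = 500,
    ftol: float = 1e-11,
    theta_init: float = 0.5,
    compute_covariance: bool = True,
    n_quad: int = 15,
) -> FitResult:
    """Fit the illness-death model by maximum likelihood.

    Quasi-Newton (L-BFGS-B) maximization of the marginal log-likelihood with
    numerical gradients; covariance from the inverse central-difference
    observed information at the optimum.
    """
    evaluator = LikelihoodEvaluator(data, spec, n_quad=n_quad)
    if start is None:
        start = _default_start(evaluator, data)
        if evaluator.spec.frailty:
            start[-1] = np.log(theta_init)
    start = np.asarray(start, dtype=float)
    ll0 = evaluator.total_loglik(start)
    if ll0 <= -1e9:
        raise ValueError("non-finite log-likelihood at the starting values")
    bounds = [(None, None)] * len(start)
    if evaluator.spec.frailty:
        bounds[-1] = (LOG_THETA_FLOOR, None)
    res = minimize(
        evaluator.negloglik,
        start,
        method="L-BFGS-B",
        bounds=bounds,
        options=dict(maxiter=max_iter, ftol=ftol, maxcor=25),
    )
    phi = res.x
    ll = evaluator.total_loglik(phi)
    grad = _numerical_gradient(evaluator.negloglik, phi)
    if evaluator.spec.frailty and phi[-1] <= LOG_THETA_FLOOR + 1e-6:
        grad[-1] = min(grad[-1], 0.0)  # boundary: only inward gradient counts
    grad_norm = float(np.max(np.abs(grad)))
    grad_tol = 1e-4 * (1.0 + abs(ll))
    converged = bool(res.success) and grad_norm < grad_tol
    cov = None
    if compute_covariance:
        H = _numerical_hessian(evaluator.negloglik, phi)
        try:
            cov = np.linalg.inv(H)
            cov = 0.5 * (cov + cov.T)
            if np.any(np.diag(cov) <= 0):
                cov = None
        except np.linalg.LinAlgError:
            cov = None
    return FitResult(
        phi=phi,
        parameter_names=evaluator.spec.parameter_names(),
        covariance=cov,
        loglik=ll,
        converged=converged,
        spec=evaluator.spec,
        n=evaluator.n,
        n_iter=int(res.nit),
        grad_norm=grad_norm,
        message=str(res.message),
        start=start,
    )


# ---------------------------------------------------------------------------
# inference


def wald_table(fit: FitResult, level: float = 0.95) -> pd.DataFrame:
    """Per-parameter Wald summary: estimate, SE, CI, z, p, and HR for betas.

    Intervals are formed on the estimation scale (log scale for theta and the
    Weibull parameters); regression coefficients are additionally reported as
    hazard ratios with exponentiated intervals.
    """
    if fit.covariance is None:
        raise ValueError("covariance unavailable for this fit")
    z = norm.ppf(0.5 + level / 2.0)
    se = fit.se
    rows = []
    for j, name in enumerate(fit.parameter_names):
        est = fit.phi[j]
        s = se[j]
        lo, hi = est - z * s, est + z * s
        zval = est / s if s > 0 else np.inf * np.sign(est) if est else 0.0
        pval = 2.0 * norm.sf(abs(zval)) if np.isfinite(zval) else 0.0
        row = dict(
            parameter=name,
            estimate=est,
            se=s,
            ci_lower=lo,
            ci_upper=hi,
            z=zval,
            p=pval,
            degenerate=bool(s == 0),
        )
        if name.startswith("beta"):
            row.update(hr=np.exp(est), hr_lower=np.exp(lo), hr_upper=np.exp(hi))
        rows.append(row)
    return pd.DataFrame(rows)


def wald_joint_test(fit: FitResult, C: np.ndarray):
    """Wald test of ``C phi = 0``; returns ``(chi2, df, p)``."""
    if fit.covariance is None:
        raise ValueError("covariance unavailable for this fit")
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if C.shape[1] != len(fit.phi):
        raise ValueError("contrast width does not match parameter count")
    if np.any(np.all(C == 0, axis=1)):
        raise ValueError("contrast matrix contains an all-zero row")
    df = np.linalg.matrix_rank(C)
    v = C @ fit.phi
    M = C @ fit.covariance @ C.T
    stat = float(v @ np.linalg.solve(M, v))
    return stat, int(df), float(chi2_dist.sf(stat, df))


def select_bspline_model(
    data: pd.DataFrame,
    covariates,
    knot_grid: Sequence[int] = (1, 2, 3),
    degree_grid: Sequence[int] = (1, 2, 3),
    candidates: Optional[Sequence[tuple]] = None,
    lambda3_clock: str = "semi_markov",
    frailty: bool = True,
    time_scale: float = 1.0,
    **fit_kwargs,
):
    """Log-likelihood model selection over B-spline knot counts and degrees.

    Candidates are ``(n_interior, degree)`` pairs applied to all three
    transitions, or explicit ``((k1,k2,k3), (d1,d2,d3))`` tuples via
    ``candidates``.  Non-converged candidates are dropped with a warning.
    Ties in log-likelihood break toward the fewest parameters.
    Returns ``(best_fit, all_fits)`` where ``all_fits`` maps candidate keys
    to FitResults.
    """
    if candidates is None:
        candidates = [((k,) * 3, (d,) * 3) for k in knot_grid for d in degree_grid]
    fits = {}
    for ks, ds in candidates:
        spec = ModelSpec.bspline(
            covariates,
            degree=tuple(ds),
            n_interior=tuple(ks),
            lambda3_clock=lambda3_clock,
            frailty=frailty,
            time_scale=time_scale,
        )
        key = (tuple(ks), tuple(ds))
        try:
            fits[key] = fit_model(data, spec, **fit_kwargs)
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"candidate {key} failed: {exc}")
    usable = {k: f for k, f in fits.items() if f.converged}
    if not usable:
        raise RuntimeError("no candidate model converged")
    for k in set(fits) - set(usable):
        warnings.warn(f"candidate {k} dropped (non-convergence)")
    best_key = min(usable, key=lambda k: (-usable[k].loglik, len(usable[k].phi)))
    return usable[best_key], fits


def baseline_hazard_function(fit: FitResult, k: int) -> Callable[[np.ndarray], np.ndarray]:
    """The fitted baseline hazard for transition ``k`` as a function of time.

    Times are on the analysis (possibly rescaled) scale used for fitting.
    """
    b = fit.spec.baselines[k - 1]
    xi = fit.params.xi[k - 1]
    if b.family == "weibull":
        alpha, kappa = np.exp(xi[0]), np.exp(xi[1])

        def haz(t):
            t = np.asarray(t, dtype=float)
            return alpha * kappa * t ** (alpha - 1.0)

        return haz
    p = BSplineHazardParams(b.degree, b.boundary_knots, b.interior_knots, xi)

    def haz(t):
        from .hazards import bspline_log_hazard

        return np.exp(bspline_log_hazard(t, p))

    return haz
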