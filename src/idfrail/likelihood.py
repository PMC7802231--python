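"""Observed-data likelihood for the shared-frailty illness-death model.

The model has three transition hazards (1: healthy->ill, 2: healthy->dead,
3: ill->dead), each multiplicative in a baseline hazard, a covariate effect
``exp(beta_k' x_k)`` and a subject-level gamma frailty ``gamma`` with mean 1
and variance ``theta``.  Data are left-truncated (subjects enter at ``L``
conditional on being event-free) and right-censored.

Each subject falls into one of four scenarios by the pair of event
indicators ``(delta1, delta2)``.  Conditional on the frailty, a subject's
likelihood contribution is a product of hazard factors at the observed event
times and survival factors, divided by the probability of being event-free
at entry, ``S1(L|gamma) S2(L|gamma)``.  Because the frailty is gamma, the
marginal (frailty-integrated) contribution is available in closed form: with
``d = delta1 + delta2`` event-time hazard factors and total cumulative-hazard
exposure ``A`` accrued between entry and exit,

    integral gamma^d exp(-gamma A) f(gamma; 1, theta) dgamma
        = [prod_{j=0}^{d-1} (1 + j theta)] * (1 + theta A)^(-(1/theta + d)).

The no-frailty model replaces the integral by ``exp(-A)``.

:class:`LikelihoodEvaluator` precomputes everything that depends only on the
data and the model specification (log event times, covariate linear-algebra,
B-spline design matrices and quadrature nodes), so that repeated evaluation
during optimization is a small number of vectorized array operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .hazards import (
    BSplineHazardParams,
    WeibullHazardParams,
    gauss_legendre_segments,
    place_knots,
)

__all__ = [
    "SubjectRecord",
    "BaselineSpec",
    "ModelSpec",
    "ParameterVector",
    "validate_records",
    "records_to_frame",
    "frailty_moment_integral",
    "cumulative_exposures",
    "subject_log_likelihood",
    "total_log_likelihood",
    "LikelihoodEvaluator",
    "LOGLIK_SENTINEL",
]

#: returned by guarded total log-likelihoods when evaluation overflows,
#: so that a line-searching optimizer can retreat
LOGLIK_SENTINEL = -1e10

REQUIRED_COLUMNS = ["L", "y1", "delta1", "y2", "delta2"]


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: entry time, two endpoint times/indicators, covariates.

    ``delta1 = 0`` encodes "no nonterminal event observed", in which case
    ``y1 == y2`` by convention (the latent illness time is taken as +inf for
    subjects who die illness-free).
    """

    L: float
    y1: float
    delta1: int
    y2: float
    delta2: int
    x1: np.ndarray = field(default_factory=lambda: np.empty(0))
    x2: np.ndarray = field(default_factory=lambda: np.empty(0))
    x3: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        msgs = _record_violations(
            self.L, self.y1, self.delta1, self.y2, self.delta2
        )
        if msgs:
            raise ValueError("invalid SubjectRecord: " + "; ".join(msgs))
        # one shared covariate vector is the common case: x1 stands in for
        # transitions 2 and 3 unless given explicitly
        for name in ("x2", "x3"):
            if getattr(self, name).size == 0 and self.x1.size:
                object.__setattr__(self, name, self.x1)


def _record_violations(L, y1, d1, y2, d2) -> list[str]:
    msgs = []
    vals = [L, y1, y2]
    if not all(np.isfinite(v) for v in vals):
        msgs.append("non-finite time")
        return msgs
    if L < 0:
        msgs.append("L < 0")
    if d1 not in (0, 1) or d2 not in (0, 1):
        msgs.append("event indicators must be 0/1")
        return msgs
    if not L < y1:
        msgs.append("violates L < y1")
    if not y1 <= y2:
        msgs.append("violates y1 <= y2")
    if d1 == 0 and y1 != y2:
        msgs.append("delta1=0 requires y1 == y2")
    if d1 == 1 and d2 == 1 and not y1 < y2:
        msgs.append("delta1=delta2=1 requires y1 < y2 (pre-jitter ties)")
    return msgs


def validate_records(df: pd.DataFrame) -> list[tuple[int, str]]:
    """Check the subject-record invariants row by row.

    Returns a list of ``(row_position, message)`` violations; empty when the
    data are valid.
    """
    report: list[tuple[int, str]] = []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    if df[REQUIRED_COLUMNS].isna().any().any():
        for i in np.nonzero(df[REQUIRED_COLUMNS].isna().any(axis=1).values)[0]:
            report.append((int(i), "missing value"))
        return report
    for i, (L, y1, d1, y2, d2) in enumerate(
        df[REQUIRED_COLUMNS].itertuples(index=False)
    ):
        for msg in _record_violations(L, y1, int(d1), y2, int(d2)):
            report.append((i, msg))
    return report


def records_to_frame(
    records: Sequence[SubjectRecord], covariate_names: Sequence[str] = ()
) -> pd.DataFrame:
    """Assemble SubjectRecords into the canonical analysis DataFrame.

    Covariates are taken from ``x1`` (the common case of one shared covariate
    vector across transitions).
    """
    rows = []
    for r in records:
        row = dict(L=r.L, y1=r.y1, delta1=r.delta1, y2=r.y2, delta2=r.delta2)
        for j, name in enumerate(covariate_names):
            row[name] = r.x1[j]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BaselineSpec:
    """Baseline hazard family for one transition.

    For ``family="bspline"``, knots may be given explicitly or resolved from
    the data (``n_interior`` knots at equally spaced percentiles of the
    transition's observed event times on its own clock).
    """

    family: str  # "weibull" | "bspline"
    degree: int = 3
    n_interior: int = 1
    boundary_knots: Optional[tuple[float, float]] = None
    interior_knots: Optional[tuple[float, ...]] = None

    def __post_init__(self):
        if self.family not in ("weibull", "bspline"):
            raise ValueError(f"unknown baseline family {self.family!r}")

    @property
    def n_params(self) -> int:
        if self.family == "weibull":
            return 2
        if self.interior_knots is not None:
            return len(self.interior_knots) + self.degree + 1
        return self.n_interior + self.degree + 1

    @property
    def knots_resolved(self) -> bool:
        return self.family == "weibull" or (
            self.boundary_knots is not None and self.interior_knots is not None
        )


@dataclass(frozen=True)
class ModelSpec:
    """Full model specification: baselines, covariates, clock, frailty.

    ``lambda3_clock`` selects how the post-illness death hazard depends on
    time: ``"semi_markov"`` (clock-reset, gap time since illness) or
    ``"markov"`` (calendar time).  ``time_scale`` divides all times at
    evaluation (e.g. 5.0 for hazard ratios per 5-year increment).
    """

    baselines: tuple[BaselineSpec, BaselineSpec, BaselineSpec]
    covariates: tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]]
    lambda3_clock: str = "semi_markov"
    frailty: bool = True
    time_scale: float = 1.0

    def __post_init__(self):
        if self.lambda3_clock not in ("markov", "semi_markov"):
            raise ValueError(f"unknown clock {self.lambda3_clock!r}")
        if not self.time_scale > 0:
            raise ValueError("time_scale must be positive")

    @classmethod
    def weibull(
        cls,
        covariates,
        lambda3_clock: str = "semi_markov",
        frailty: bool = True,
        time_scale: float = 1.0,
    ) -> "ModelSpec":
        cov = _normalize_covariates(covariates)
        b = BaselineSpec("weibull")
        return cls((b, b, b), cov, lambda3_clock, frailty, time_scale)

    @classmethod
    def bspline(
        cls,
        covariates,
        degree=3,
        n_interior=1,
        lambda3_clock: str = "semi_markov",
        frailty: bool = True,
        time_scale: float = 1.0,
    ) -> "ModelSpec":
        cov = _normalize_covariates(covariates)
        degs = degree if isinstance(degree, (tuple, list)) else (degree,) * 3
        ks = n_interior if isinstance(n_interior, (tuple, list)) else (n_interior,) * 3
        bs = tuple(BaselineSpec("bspline", d, k) for d, k in zip(degs, ks))
        return cls(bs, cov, lambda3_clock, frailty, time_scale)

    @property
    def n_params(self) -> int:
        return (
            sum(b.n_params for b in self.baselines)
            + sum(len(c) for c in self.covariates)
            + (1 if self.frailty else 0)
        )

    def parameter_names(self) -> list[str]:
        names = []
        for k, b in enumerate(self.baselines, start=1):
            if b.family == "weibull":
                names += [f"log_alpha{k}", f"log_kappa{k}"]
            else:
                names += [f"eta{k}_{j}" for j in range(b.n_params)]
        for k, cov in enumerate(self.covariates, start=1):
            names += [f"beta{k}_{c}" for c in cov]
        if self.frailty:
            names.append("log_theta")
        return names


def _normalize_covariates(covariates) -> tuple[tuple[str, ...], ...]:
    if isinstance(covariates, str):
        covariates = [covariates]
    if covariates and isinstance(covariates[0], str):
        covariates = [covariates, covariates, covariates]
    return tuple(tuple(c) for c in covariates)


@dataclass(frozen=True)
class ParameterVector:
    """Packed model parameters: (xi1, xi2, xi3, beta1, beta2, beta3, log theta).

    ``xi_k`` is the transition-k baseline block — ``(log alpha, log kappa)``
    for Weibull, the control points ``eta`` for B-splines.  ``log_theta`` is
    present iff the model has a frailty.
    """

    xi: tuple[np.ndarray, np.ndarray, np.ndarray]
    beta: tuple[np.ndarray, np.ndarray, np.ndarray]
    log_theta: Optional[float] = None

    def to_array(self) -> np.ndarray:
        parts = [np.atleast_1d(np.asarray(b, dtype=float)) for b in self.xi]
        parts += [np.atleast_1d(np.asarray(b, dtype=float)) for b in self.beta]
        if self.log_theta is not None:
            parts.append(np.array([self.log_theta]))
        return np.concatenate(parts) if parts else np.empty(0)

    @classmethod
    def from_array(cls, arr: np.ndarray, spec: ModelSpec) -> "ParameterVector":
        arr = np.asarray(arr, dtype=float)
        if arr.size != spec.n_params:
            raise ValueError(
                f"parameter vector length {arr.size} != expected {spec.n_params}"
            )
        pos = 0
        xi = []
        for b in spec.baselines:
            xi.append(arr[pos : pos + b.n_params].copy())
            pos += b.n_params
        beta = []
        for cov in spec.covariates:
            beta.append(arr[pos : pos + len(cov)].copy())
            pos += len(cov)
        log_theta = float(arr[pos]) if spec.frailty else None
        return cls(tuple(xi), tuple(beta), log_theta)

    @property
    def theta(self) -> Optional[float]:
        return None if self.log_theta is None else float(np.exp(self.log_theta))


def frailty_moment_integral(d: int, A, theta: float):
    """Closed-form gamma-frailty moment integral.

    ``integral gamma^d exp(-gamma A) f(gamma) dgamma`` for gamma ~ Gamma with
    mean 1 and variance ``theta`` (shape ``1/theta``, scale ``theta``):
    ``[prod_{j=0}^{d-1}(1 + j theta)] (1 + theta A)^(-(1/theta + d))``.
    """
    if theta <= 0:
        raise ValueError("theta must be positive (use the no-frailty path)")
    if d not in (0, 1, 2):
        raise ValueError("d must be 0, 1 or 2")
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ValueError("A must be nonnegative (cumulative-hazard ordering)")
    prefac = 1.0
    for j in range(d):
        prefac *= 1.0 + j * theta
    out = prefac * np.exp(-(1.0 / theta + d) * np.log1p(theta * A))
    return float(out) if out.ndim == 0 else out


class LikelihoodEvaluator:
    """Vectorized log-likelihood for a fixed dataset and model spec.

    Construction validates the data, applies the time scale, resolves
    B-spline knots from the observed event times (unless supplied), and
    precomputes design matrices and quadrature rules.  After construction
    :meth:`total_loglik` is a pure function of the packed parameter array.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec, n_quad: int = 15):
        report = validate_records(data)
        if report:
            lines = "; ".join(f"row {i}: {m}" for i, m in report[:10])
            raise ValueError(f"invalid subject records ({len(report)}): {lines}")
        self.spec_input = spec
        s = spec.time_scale
        self.L = data["L"].to_numpy(dtype=float) / s
        self.y1 = data["y1"].to_numpy(dtype=float) / s
        self.y2 = data["y2"].to_numpy(dtype=float) / s
        self.d1 = data["delta1"].to_numpy(dtype=int)
        self.d2 = data["delta2"].to_numpy(dtype=int)
        self.n = len(self.y1)
        self.X = tuple(
            data[list(cov)].to_numpy(dtype=float) if cov else np.empty((self.n, 0))
            for cov in spec.covariates
        )
        self.m1 = self.d1 == 1
        self.m2 = (self.d1 == 0) & (self.d2 == 1)
        self.m3 = (self.d1 == 1) & (self.d2 == 1)
        self.gap = np.where(self.m1, self.y2 - self.y1, 0.0)
        if np.any(~np.isfinite(self.X[0])) if self.X[0].size else False:
            raise ValueError("non-finite covariates")

        # resolve knots where needed, then freeze the spec echo
        resolved = []
        for k, b in enumerate(spec.baselines):
            if b.family == "bspline" and not b.knots_resolved:
                ev, mf = self._transition_times(k, spec.lambda3_clock)
                boundary, interior = place_knots(ev, b.n_interior, mf)
                b = replace(b, boundary_knots=boundary, interior_knots=interior)
            resolved.append(b)
        self.spec = replace(spec, baselines=tuple(resolved))

        with np.errstate(divide="ignore"):
            self._log_y1 = np.log(self.y1)
            self._log_L = np.where(self.L > 0, np.log(self.L), -np.inf)
            g = self.gap[self.m3]
            self._log_clock3 = (
                np.log(g)
                if spec.lambda3_clock == "semi_markov"
                else np.log(self.y2[self.m3])
            )
            self._log_y1_m3 = np.log(self.y1[self.m3])

        # B-spline machinery per transition
        self._bspline = {}
        for k, b in enumerate(self.spec.baselines):
            if b.family != "bspline":
                continue
            full = BSplineHazardParams(
                b.degree, b.boundary_knots, b.interior_knots, np.zeros(b.n_params)
            )
            knots, bp, deg = full.full_knots, full.breakpoints, b.degree
            from scipy.interpolate import BSpline as _BS

            def check(t, lo=bp[0], hi=bp[-1], kk=k):
                t = np.asarray(t, dtype=float)
                if t.size and (t.min() < lo - 1e-12 or t.max() > hi + 1e-12):
                    raise ValueError(
                        f"transition {kk + 1}: time outside B-spline knot "
                        f"range [{lo}, {hi}]"
                    )
                return np.clip(t, lo, hi)

            def design(t, _check=check, _knots=knots, _deg=deg):
                return _BS.design_matrix(_check(t), _knots, _deg).toarray()

            def quad(t, _check=check, _bp=bp, _knots=knots, _deg=deg):
                return gauss_legendre_segments(_bp, _deg, _knots, _check(t), n_quad)

            entry = {"params": full}
            if k in (0, 1):
                entry["quad_y1"] = quad(self.y1)
                entry["quad_L"] = quad(self.L)
                ev_times = self.y1[self.m1] if k == 0 else self.y1[self.m2]
                entry["design_event"] = design(ev_times)
            else:
                if spec.lambda3_clock == "semi_markov":
                    entry["quad_a"] = quad(self.gap[self.m1])
                else:
                    entry["quad_a"] = quad(self.y2[self.m1])
                    entry["quad_b"] = quad(self.y1[self.m1])
                clock3 = (
                    self.gap[self.m3]
                    if spec.lambda3_clock == "semi_markov"
                    else self.y2[self.m3]
                )
                entry["design_event"] = design(clock3)
            self._bspline[k] = entry

        # parameter slicing
        self._slices = []
        pos = 0
        for b in self.spec.baselines:
            self._slices.append(slice(pos, pos + b.n_params))
            pos += b.n_params
        for cov in self.spec.covariates:
            self._slices.append(slice(pos, pos + len(cov)))
            pos += len(cov)
        self._theta_index = pos if self.spec.frailty else None

    def _transition_times(self, k: int, clock: str):
        """Observed event times and max follow-up for transition k's clock."""
        if k == 0:
            ev = self.y1[self.m1]
            mf = self.y1.max()
        elif k == 1:
            ev = self.y1[self.m2]
            mf = self.y1.max()
        else:
            if not np.any(self.m1):
                raise ValueError("no subjects at risk for transition 3")
            if clock == "semi_markov":
                ev = self.gap[self.m3]
                mf = self.gap[self.m1].max()
            else:
                ev = self.y2[self.m3]
                mf = self.y2[self.m1].max()
        if ev.size == 0:
            raise ValueError(f"no observed events for transition {k + 1}")
        return ev, mf

    # -- parameter access -------------------------------------------------
    def unpack(self, phi: np.ndarray) -> ParameterVector:
        return ParameterVector.from_array(phi, self.spec)

    def _blocks(self, phi):
        phi = np.asarray(phi, dtype=float)
        xi = [phi[self._slices[k]] for k in range(3)]
        beta = [phi[self._slices[3 + k]] for k in range(3)]
        theta = np.exp(phi[self._theta_index]) if self.spec.frailty else None
        return xi, beta, theta

    # -- baseline pieces --------------------------------------------------
    def _cumhaz_weibull(self, xi, log_t):
        # exp(log kappa + alpha * log t); log t = -inf at t=0 gives 0
        alpha = np.exp(xi[0])
        return np.exp(xi[1] + alpha * log_t)

    def _transition_cumhaz(self, k, xi):
        """(cumhaz at y1, cumhaz at L) for k in (0, 1) on the full sample."""
        b = self.spec.baselines[k]
        if b.family == "weibull":
            return (
                self._cumhaz_weibull(xi, self._log_y1),
                self._cumhaz_weibull(xi, self._log_L),
            )
        e = self._bspline[k]
        return e["quad_y1"].cumulative(xi), e["quad_L"].cumulative(xi)

    def _transition3_exposure_baseline(self, xi):
        """Baseline lambda3 exposure (before covariates) among delta1=1 rows."""
        b = self.spec.baselines[2]
        if b.family == "weibull":
            alpha, kappa = np.exp(xi[0]), np.exp(xi[1])
            if self.spec.lambda3_clock == "semi_markov":
                return kappa * self.gap[self.m1] ** alpha
            return kappa * (self.y2[self.m1] ** alpha - self.y1[self.m1] ** alpha)
        e = self._bspline[2]
        if self.spec.lambda3_clock == "semi_markov":
            return e["quad_a"].cumulative(xi)
        return e["quad_a"].cumulative(xi) - e["quad_b"].cumulative(xi)

    def exposures(self, phi):
        """Per-subject covariate-adjusted cumulative-hazard exposures.

        Returns ``(A, H1y1, H2y1, H1L, H2L, H3)`` where ``A`` is the net
        exposure entering the frailty integral and ``H3`` is zero for
        subjects without the nonterminal event.
        """
        xi, beta, _ = self._blocks(phi)
        lp = [
            self.X[k] @ beta[k] if beta[k].size else np.zeros(self.n)
            for k in range(3)
        ]
        H1y1_0, H1L_0 = self._transition_cumhaz(0, xi[0])
        H2y1_0, H2L_0 = self._transition_cumhaz(1, xi[1])
        H1y1 = H1y1_0 * np.exp(lp[0])
        H1L = H1L_0 * np.exp(lp[0])
        H2y1 = H2y1_0 * np.exp(lp[1])
        H2L = H2L_0 * np.exp(lp[1])
        H3 = np.zeros(self.n)
        if np.any(self.m1):
            H3[self.m1] = self._transition3_exposure_baseline(xi[2]) * np.exp(
                lp[2][self.m1]
            )
        A = H1y1 + H2y1 + H3 - H1L - H2L
        return np.maximum(A, 0.0), H1y1, H2y1, H1L, H2L, H3

    def subject_loglik(self, phi) -> np.ndarray:
        """Per-subject marginal log-likelihood contributions."""
        # overflow in extreme parameter regions is expected during line
        # search and handled by the sentinel in total_loglik
        with np.errstate(over="ignore", invalid="ignore"):
            return self._subject_loglik(phi)

    def _subject_loglik(self, phi) -> np.ndarray:
        xi, beta, theta = self._blocks(phi)
        A = self.exposures(phi)[0]
        d = self.d1 + self.d2
        ll = np.zeros(self.n)
        # event-rate log factors, per subject
        specs = self.spec.baselines
        if specs[0].family == "weibull":
            lh1 = xi[0][0] + xi[0][1] + (np.exp(xi[0][0]) - 1.0) * self._log_y1[self.m1]
        else:
            lh1 = self._bspline[0]["design_event"] @ xi[0]
        ll[self.m1] += lh1 + (
            self.X[0][self.m1] @ beta[0] if beta[0].size else 0.0
        )
        if specs[1].family == "weibull":
            lh2 = xi[1][0] + xi[1][1] + (np.exp(xi[1][0]) - 1.0) * self._log_y1[self.m2]
        else:
            lh2 = self._bspline[1]["design_event"] @ xi[1]
        ll[self.m2] += lh2 + (
            self.X[1][self.m2] @ beta[1] if beta[1].size else 0.0
        )
        if specs[2].family == "weibull":
            lh3 = xi[2][0] + xi[2][1] + (np.exp(xi[2][0]) - 1.0) * self._log_clock3
        else:
            lh3 = self._bspline[2]["design_event"] @ xi[2]
        ll[self.m3] += lh3 + (
            self.X[2][self.m3] @ beta[2] if beta[2].size else 0.0
        )
        if theta is None:
            ll -= A
        else:
            ll += np.where(d == 2, np.log1p(theta), 0.0)
            ll -= (1.0 / theta + d) * np.log1p(theta * A)
        return ll

    def total_loglik(self, phi, guard: bool = True) -> float:
        total = float(np.sum(self.subject_loglik(phi)))
        if not np.isfinite(total):
            if guard:
                return LOGLIK_SENTINEL
            raise FloatingPointError("non-finite log-likelihood")
        return total

    def negloglik(self, phi) -> float:
        return -self.total_loglik(phi)


# -- convenience record-level API -----------------------------------------


def _single_frame(rec: SubjectRecord, spec: ModelSpec) -> pd.DataFrame:
    names = sorted({c for cov in spec.covariates for c in cov})
    row = dict(L=rec.L, y1=rec.y1, delta1=rec.delta1, y2=rec.y2, delta2=rec.delta2)
    xs = {1: rec.x1, 2: rec.x2, 3: rec.x3}
    for name in names:
        for k, cov in enumerate(spec.covariates, start=1):
            if name in cov:
                row[name] = float(np.atleast_1d(xs[k])[cov.index(name)])
    return pd.DataFrame([row])


def cumulative_exposures(rec: SubjectRecord, phi: ParameterVector, spec: ModelSpec):
    """Covariate-adjusted cumulative-hazard exposures for one subject.

    Returns a dict with keys ``H1_y1, H2_y1, H1_L, H2_L, H3, A``.
    """
    ev = LikelihoodEvaluator(_single_frame(rec, spec), spec)
    A, H1y1, H2y1, H1L, H2L, H3 = ev.exposures(phi.to_array())
    return dict(
        H1_y1=float(H1y1[0]),
        H2_y1=float(H2y1[0]),
        H1_L=float(H1L[0]),
        H2_L=float(H2L[0]),
        H3=float(H3[0]),
        A=float(A[0]),
    )


def subject_log_likelihood(
    rec: SubjectRecord, phi: ParameterVector, spec: ModelSpec
) -> float:
    """Marginal log-likelihood contribution of a single subject."""
    ev = LikelihoodEvaluator(_single_frame(rec, spec), spec)
    ll = ev.subject_loglik(phi.to_array())
    if not np.isfinite(ll[0]):
        raise FloatingPointError("non-finite log-likelihood for subject record")
    return float(ll[0])


def total_log_likelihood(
    data: pd.DataFrame, phi: ParameterVector | np.ndarray, spec: ModelSpec
) -> float:
    """Total marginal log-likelihood over a validated dataset.

    Overflow is guarded: a large negative sentinel is returned instead of
    ``-inf``/``nan`` so optimizers can retreat.
    """
    if len(data) == 0:
        raise ValueError("empty dataset")
    arr = phi.to_array() if isinstance(phi, ParameterVector) else np.asarray(phi)
    return LikelihoodEvaluator(data, spec).total_loglik(arr)
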