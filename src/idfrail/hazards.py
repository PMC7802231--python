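"""Baseline hazard families for illness-death transition models.

Two parametric families are supported for each transition-specific baseline
hazard :math:`\\lambda_{k,0}(t)`:

* **Weibull**: :math:`\\lambda_0(t) = \\alpha \\kappa t^{\\alpha-1}`, with
  cumulative hazard :math:`\\Lambda_0(t) = \\kappa t^{\\alpha}`.  Both
  parameters are handled on the log scale so that the optimizer works on an
  unconstrained space.
* **B-spline log-hazard**: :math:`\\log \\lambda_0(t) = B(t) = \\sum_b
  \\eta_b B_{b,d}(t)`, a degree-``d`` spline with unique knots
  :math:`0 = t_0 < t_1 < \\dots < t_{K+1}` where :math:`t_{K+1}` is the
  largest follow-up time.  The cumulative hazard has no closed form and is
  evaluated by composite Gauss-Legendre quadrature over inter-knot segments.

Hazards are defined only on their stated domain: the B-spline family raises
on evaluation outside ``[t0, tK+1]`` rather than extrapolating, and the
Weibull hazard raises at ``t = 0`` when ``alpha < 1`` (the hazard is infinite
there).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "WeibullHazardParams",
    "BSplineHazardParams",
    "weibull_hazard",
    "weibull_log_hazard",
    "weibull_cumulative_hazard",
    "bspline_basis",
    "bspline_log_hazard",
    "bspline_cumulative_hazard",
    "place_knots",
    "gauss_legendre_segments",
]


@dataclass(frozen=True)
class WeibullHazardParams:
    """Weibull baseline hazard, parameterized on the log scale.

    ``alpha = exp(log_alpha)`` is the shape, ``kappa = exp(log_kappa)`` the
    rate-scale, giving hazard ``alpha * kappa * t**(alpha - 1)``.
    """

    log_alpha: float
    log_kappa: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.log_alpha) and np.isfinite(self.log_kappa)):
            raise ValueError("Weibull log-parameters must be finite")

    @property
    def alpha(self) -> float:
        return float(np.exp(self.log_alpha))

    @property
    def kappa(self) -> float:
        return float(np.exp(self.log_kappa))


@dataclass(frozen=True)
class BSplineHazardParams:
    """B-spline log baseline hazard.

    The user supplies *unique* knots: a boundary pair ``(t0, tK1)`` and
    strictly increasing interior knots inside the boundaries.  Boundary knots
    are repeated ``degree + 1`` times internally (clamped spline).  The basis
    dimension, and hence the length of ``control_points``, is
    ``K + degree + 1`` where ``K`` is the number of interior knots.
    """

    degree: int
    boundary_knots: tuple[float, float]
    interior_knots: tuple[float, ...]
    control_points: np.ndarray

    def __post_init__(self) -> None:
        if self.degree < 0:
            raise ValueError("degree must be >= 0")
        t0, t1 = self.boundary_knots
        knots = (t0, *self.interior_knots, t1)
        if not all(a < b for a, b in zip(knots, knots[1:])):
            raise ValueError("knots must be strictly increasing within boundaries")
        eta = np.asarray(self.control_points, dtype=float)
        if eta.ndim != 1 or eta.size != self.basis_dimension:
            raise ValueError(
                f"expected {self.basis_dimension} control points, got {eta.size}"
            )
        if not np.all(np.isfinite(eta)):
            raise ValueError("control points must be finite")
        object.__setattr__(self, "control_points", eta)

    @property
    def n_interior(self) -> int:
        return len(self.interior_knots)

    @property
    def basis_dimension(self) -> int:
        return self.n_interior + self.degree + 1

    @property
    def breakpoints(self) -> np.ndarray:
        """Unique knot sequence t0 < t1 < ... < tK+1."""
        return np.array(
            [self.boundary_knots[0], *self.interior_knots, self.boundary_knots[1]]
        )

    @property
    def full_knots(self) -> np.ndarray:
        """Clamped knot vector with boundaries repeated degree+1 times."""
        d = self.degree
        return np.concatenate(
            [
                np.repeat(self.boundary_knots[0], d + 1),
                np.asarray(self.interior_knots, dtype=float),
                np.repeat(self.boundary_knots[1], d + 1),
            ]
        )


def _check_times(t: np.ndarray, lo: float, hi: float, what: str) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < lo) or np.any(t > hi):
        raise ValueError(f"{what}: time outside [{lo}, {hi}]")
    return t


def weibull_hazard(t, p: WeibullHazardParams):
    """Hazard ``alpha * kappa * t**(alpha-1)``; raises at t=0 if alpha < 1."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    alpha = p.alpha
    if alpha < 1 and np.any(t == 0):
        raise ValueError("hazard is infinite at t=0 for alpha < 1")
    with np.errstate(divide="ignore"):
        out = np.exp(weibull_log_hazard(np.where(t > 0, t, 1.0), p))
    out = np.where(t > 0, out, alpha * p.kappa * 0.0 if alpha > 1 else p.kappa)
    # alpha == 1 exactly: hazard kappa at 0; alpha > 1: hazard 0 at 0
    return out if out.ndim else float(out)


def weibull_log_hazard(t, p: WeibullHazardParams):
    """log hazard = log_alpha + log_kappa + (alpha-1) log t (t > 0)."""
    t = np.asarray(t, dtype=float)
    return p.log_alpha + p.log_kappa + (p.alpha - 1.0) * np.log(t)


def weibull_cumulative_hazard(t, p: WeibullHazardParams):
    """Cumulative hazard ``kappa * t**alpha``; 0 at t=0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    out = p.kappa * t**p.alpha
    return out if out.ndim else float(out)


def bspline_basis(t, degree: int, params_or_knots) -> np.ndarray:
    """Evaluate all B-spline basis functions at ``t``.

    ``params_or_knots`` is either a :class:`BSplineHazardParams` or a full
    (clamped) knot vector.  Returns an array of shape ``(len(t), dim)`` (or
    ``(dim,)`` for scalar ``t``) whose rows sum to one.
    """
    if isinstance(params_or_knots, BSplineHazardParams):
        knots = params_or_knots.full_knots
    else:
        knots = np.asarray(params_or_knots, dtype=float)
    scalar = np.isscalar(t) or np.ndim(t) == 0
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    _check_times(t_arr, knots[0], knots[-1], "bspline_basis")
    D = BSpline.design_matrix(t_arr, knots, degree).toarray()
    return D[0] if scalar else D


def bspline_log_hazard(t, p: BSplineHazardParams):
    """log hazard = sum_b eta_b B_{b,d}(t) on [t0, tK+1]."""
    D = bspline_basis(t, p.degree, p)
    return D @ p.control_points


def bspline_cumulative_hazard(t, p: BSplineHazardParams, n_nodes: int = 15):
    """Cumulative hazard ``int_0^t exp(B(u)) du`` by segment-wise quadrature.

    Composite Gauss-Legendre with ``n_nodes`` nodes per inter-knot segment
    (full segments below ``t`` plus a partial final segment).
    """
    scalar = np.isscalar(t) or np.ndim(t) == 0
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    bp = p.breakpoints
    _check_times(t_arr, bp[0], bp[-1], "bspline_cumulative_hazard")
    quad = gauss_legendre_segments(bp, p.degree, p.full_knots, t_arr, n_nodes)
    out = quad.cumulative(p.control_points)
    return float(out[0]) if scalar else out


class gauss_legendre_segments:
    """Precomputed quadrature structure for ``int_0^t exp(B(u)) du``.

    Everything that depends only on the knots and the evaluation times is
    computed once; :meth:`cumulative` is then a cheap function of the control
    points, which makes repeated likelihood evaluation fast.
    """

    def __init__(
        self,
        breakpoints: np.ndarray,
        degree: int,
        full_knots: np.ndarray,
        times: np.ndarray,
        n_nodes: int = 15,
    ):
        x, w = np.polynomial.legendre.leggauss(n_nodes)
        bp = np.asarray(breakpoints, dtype=float)
        times = np.asarray(times, dtype=float)
        n_seg = len(bp) - 1
        a, b = bp[:-1], bp[1:]
        # full-segment nodes: (n_seg, n_nodes)
        seg_nodes = a[:, None] + (b - a)[:, None] * (x[None, :] + 1.0) / 2.0
        self._seg_w = (b - a)[:, None] / 2.0 * w[None, :]
        self._seg_D = BSpline.design_matrix(
            seg_nodes.ravel(), full_knots, degree
        ).toarray()
        self._n_seg, self._n_nodes = n_seg, n_nodes
        # segment index of each time: number of *complete* segments below t
        idx = np.clip(np.searchsorted(bp, times, side="right") - 1, 0, n_seg - 1)
        self._idx = idx
        lo = bp[idx]
        # partial-segment nodes mapped onto [lo, t]
        part_nodes = lo[:, None] + (times - lo)[:, None] * (x[None, :] + 1.0) / 2.0
        self._part_w = (times - lo)[:, None] / 2.0 * w[None, :]
        self._part_D = BSpline.design_matrix(
            part_nodes.ravel(), full_knots, degree
        ).toarray()
        self._n_times = len(times)

    def cumulative(self, eta: np.ndarray) -> np.ndarray:
        """Cumulative hazard at the stored times, for control points ``eta``."""
        f_seg = np.exp(self._seg_D @ eta).reshape(self._n_seg, self._n_nodes)
        seg_int = np.einsum("sn,sn->s", f_seg, self._seg_w)
        cum_at_break = np.concatenate([[0.0], np.cumsum(seg_int)])
        f_part = np.exp(self._part_D @ eta).reshape(self._n_times, self._n_nodes)
        part = np.einsum("tn,tn->t", f_part, self._part_w)
        return cum_at_break[self._idx] + part


def place_knots(
    event_times: Sequence[float],
    n_interior: int,
    max_follow_up: float,
) -> tuple[tuple[float, float], tuple[float, ...]]:
    """Boundary and interior knots for a B-spline baseline hazard.

    Interior knots sit at equally spaced percentiles ``100*j/(n_interior+1)``
    of the observed event times (linear-interpolation quantiles); boundary
    knots are ``(0, max_follow_up)``.
    """
    ev = np.asarray(event_times, dtype=float)
    if ev.size == 0:
        raise ValueError("event_times must be nonempty")
    if np.any(ev <= 0):
        raise ValueError("event times must be positive")
    if max_follow_up < ev.max():
        raise ValueError("max_follow_up must be >= max(event_times)")
    qs = [100.0 * j / (n_interior + 1) for j in range(1, n_interior + 1)]
    interior = np.percentile(ev, qs, method="linear")
    seq = np.concatenate([[0.0], interior, [max_follow_up]])
    if not np.all(np.diff(seq) > 0):
        raise ValueError(
            "knot percentiles collapse (heavily tied event times); "
            "use fewer interior knots"
        )
    return (0.0, float(max_follow_up)), tuple(float(v) for v in interior)
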