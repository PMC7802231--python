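"""Simulation-study harness: operating characteristics of the fitters.

Repeatedly simulates datasets from a :class:`~idfrail.simulate.SimulationDesign`,
fits one or more model specifications to each replicate, and summarizes the
sampling distribution of the estimators: mean estimate, mean analytic
standard error (SEa, from the observed information), empirical standard
error (SEe, the SD of the estimates across replicates), and coverage of 95%
Wald confidence intervals, all on the estimation scale (log scale for the
frailty variance and Weibull baseline parameters).

Also provides the integrated squared error (ISE)
``int (hazard_hat(t) - hazard_true(t))^2 dt`` between fitted and true
baseline hazards, evaluated over the range of observed event times, with the
median across replicates as the summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import simpson

from .fit import FitResult, baseline_hazard_function, fit_model
from .likelihood import ModelSpec
from .simulate import SimulationDesign, simulate_dataset

__all__ = [
    "OperatingCharacteristics",
    "operating_characteristics",
    "integrated_squared_error",
    "true_parameter_map",
    "run_study",
    "StudyResult",
]

Z95 = 1.959964


@dataclass
class OperatingCharacteristics:
    """Summary table over replicates plus convergence bookkeeping."""

    table: pd.DataFrame  # parameter, truth, mean_est, mean_se_a, se_e, coverage
    n_replicates: int
    n_converged: int


def operating_characteristics(
    estimates: np.ndarray,
    ses: np.ndarray,
    truth: np.ndarray,
    parameter_names: Optional[Sequence[str]] = None,
) -> OperatingCharacteristics:
    """Column-wise operating characteristics of an estimator.

    ``estimates`` and ``ses`` are (replicates x parameters); coverage is the
    fraction of replicates with ``|est - truth| <= 1.959964 * se``.
    """
    est = np.atleast_2d(np.asarray(estimates, float))
    se = np.atleast_2d(np.asarray(ses, float))
    truth = np.asarray(truth, float)
    if est.shape != se.shape or est.shape[1] != truth.size:
        raise ValueError("shape mismatch between estimates, SEs and truth")
    if est.shape[0] < 2:
        raise ValueError("need at least 2 replicates")
    if parameter_names is None:
        parameter_names = [f"p{j}" for j in range(est.shape[1])]
    cover = np.mean(np.abs(est - truth) <= Z95 * se, axis=0)
    table = pd.DataFrame(
        dict(
            parameter=list(parameter_names),
            truth=truth,
            mean_est=est.mean(axis=0),
            mean_se_a=se.mean(axis=0),
            se_e=est.std(axis=0, ddof=1),
            coverage=cover,
        )
    )
    return OperatingCharacteristics(table, est.shape[0], est.shape[0])


def integrated_squared_error(
    estimated: Callable[[np.ndarray], np.ndarray],
    true: Callable[[np.ndarray], np.ndarray],
    t_range: tuple[float, float],
    n_points: int = 513,
) -> float:
    """``int (estimated - true)^2 dt`` by composite Simpson quadrature."""
    lo, hi = t_range
    if not hi > lo:
        raise ValueError("empty integration range")
    t = np.linspace(lo, hi, n_points)
    diff = np.asarray(estimated(t), float) - np.asarray(true(t), float)
    return float(simpson(diff**2, x=t))


def true_parameter_map(design: SimulationDesign, spec: ModelSpec) -> dict[str, float]:
    """Truth values, keyed by the fitted model's parameter names.

    Weibull fits are compared on all parameters; flexible-baseline fits only
    on the regression coefficients and the log frailty variance.
    """
    out: dict[str, float] = {}
    for k, b in enumerate(spec.baselines, start=1):
        if b.family == "weibull":
            out[f"log_alpha{k}"] = design.log_alpha[k - 1]
            out[f"log_kappa{k}"] = design.log_kappa[k - 1]
    for k, cov in enumerate(spec.covariates, start=1):
        for c in cov:
            if c == design.covariate_name:
                out[f"beta{k}_{c}"] = design.beta[k - 1]
    if spec.frailty and design.log_theta is not None:
        out["log_theta"] = design.log_theta
    return out


def _true_hazard(design: SimulationDesign, k: int) -> Callable:
    alpha = np.exp(design.log_alpha[k - 1])
    kappa = np.exp(design.log_kappa[k - 1])

    def haz(t):
        t = np.asarray(t, float)
        return alpha * kappa * t ** (alpha - 1.0)

    return haz


def _event_range(df: pd.DataFrame, k: int, clock: str) -> Optional[tuple[float, float]]:
    d1 = df["delta1"].to_numpy(int)
    d2 = df["delta2"].to_numpy(int)
    if k == 1:
        ev = df["y1"].to_numpy(float)[d1 == 1]
    elif k == 2:
        ev = df["y1"].to_numpy(float)[(d1 == 0) & (d2 == 1)]
    else:
        m3 = (d1 == 1) & (d2 == 1)
        if clock == "semi_markov":
            ev = (df["y2"].to_numpy(float) - df["y1"].to_numpy(float))[m3]
        else:
            ev = df["y2"].to_numpy(float)[m3]
    if ev.size < 2 or ev.max() <= ev.min():
        return None
    return float(ev.min()), float(ev.max())


@dataclass
class StudyResult:
    """Archive and summaries from :func:`run_study`."""

    estimates: pd.DataFrame  # long: replicate, spec, parameter, estimate, se, converged
    summaries: dict[str, OperatingCharacteristics]
    ise: pd.DataFrame  # replicate, spec, transition, ise
    design: SimulationDesign


def summarize_archive(
    archive: pd.DataFrame,
    truth_maps: Mapping[str, Mapping[str, float]],
) -> dict[str, OperatingCharacteristics]:
    """Operating characteristics per fit spec from the long-format archive.

    Non-convergent replicates are excluded from the summaries but counted.
    Deterministic under permutation of archive rows.
    """
    out = {}
    for name, truth in truth_maps.items():
        sub = archive[archive["spec"] == name]
        n_total = sub["replicate"].nunique()
        ok = sub[sub["converged"]]
        params = [p for p in truth if p in set(ok["parameter"])]
        est = ok.pivot_table(
            index="replicate", columns="parameter", values="estimate", sort=True
        )[params].sort_index()
        se = ok.pivot_table(
            index="replicate", columns="parameter", values="se", sort=True
        )[params].sort_index()
        oc = operating_characteristics(
            est.to_numpy(), se.to_numpy(), np.array([truth[p] for p in params]), params
        )
        oc = OperatingCharacteristics(oc.table, n_total, est.shape[0])
        out[name] = oc
    return out


def run_study(
    design: SimulationDesign,
    fit_specs: Mapping[str, ModelSpec],
    R: int,
    seed: int = 0,
    compute_ise: bool = False,
    fit_kwargs: Optional[Mapping[str, dict]] = None,
    progress: bool = False,
) -> StudyResult:
    """Simulate ``R`` replicates, fit each spec to each, and summarize.

    Replicate seeds are spawned deterministically from ``seed``.  A spec for
    which every replicate fails to converge raises.
    """
    if R < 2:
        raise ValueError("need at least R=2 replicates")
    fit_kwargs = dict(fit_kwargs or {})
    rep_seeds = np.random.SeedSequence(seed).generate_state(R) & 0x7FFFFFFF
    rows, ise_rows = [], []
    for r in range(R):
        d = replace(design, seed=int(rep_seeds[r]))
        df, _ = simulate_dataset(d)
        for name, spec in fit_specs.items():
            try:
                fit = fit_model(df, spec, **fit_kwargs.get(name, {}))
            except (ValueError, np.linalg.LinAlgError) as exc:
                warnings.warn(f"replicate {r}, spec {name!r}: {exc}")
                continue
            se = fit.se
            usable = fit.converged and se is not None
            for j, pname in enumerate(fit.parameter_names):
                rows.append(
                    dict(
                        replicate=r,
                        spec=name,
                        parameter=pname,
                        estimate=fit.phi[j],
                        se=se[j] if se is not None else np.nan,
                        converged=usable,
                    )
                )
            if compute_ise and usable:
                for k in (1, 2, 3):
                    rng_k = _event_range(df, k, spec.lambda3_clock)
                    if rng_k is None:
                        continue
                    ise_rows.append(
                        dict(
                            replicate=r,
                            spec=name,
                            transition=k,
                            ise=integrated_squared_error(
                                baseline_hazard_function(fit, k),
                                _true_hazard(design, k),
                                rng_k,
                            ),
                        )
                    )
        if progress:
            print(f"replicate {r + 1}/{R} done", flush=True)
    archive = pd.DataFrame(rows)
    if archive.empty:
        raise RuntimeError("no replicate produced a fit")
    truth_maps = {
        name: true_parameter_map(design, spec) for name, spec in fit_specs.items()
    }
    summaries = {}
    for name in fit_specs:
        sub = archive[(archive["spec"] == name) & archive["converged"]]
        if sub.empty:
            raise RuntimeError(f"all replicates non-convergent for spec {name!r}")
    summaries = summarize_archive(archive, truth_maps)
    ise = pd.DataFrame(ise_rows, columns=["replicate", "spec", "transition", "ise"])
    return StudyResult(archive, summaries, ise, design)
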