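"""Readers and writers: datasets, fit serialization, study outputs.

Datasets are plain CSV with columns ``id, L, y1, delta1, y2, delta2`` plus
covariates by name.  Output files carry a comment header (``#`` lines) with
the package version, seed and a configuration hash so that runs are
reproducible and self-describing.  Times are stored on the original scale;
any ``time_scale`` divisor is part of the model specification and applied at
likelihood evaluation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .fit import FitResult
from .likelihood import (
    BaselineSpec,
    LikelihoodEvaluator,
    ModelSpec,
    validate_records,
)
from .study import StudyResult

__all__ = [
    "read_dataset",
    "write_dataset",
    "fit_to_dict",
    "fit_from_dict",
    "write_fit_json",
    "read_fit_json",
    "write_study_outputs",
    "config_hash",
]


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _comment_header(seed: Optional[int], config: Optional[dict]) -> str:
    lines = [f"# idfrail {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config: {config_hash(config)}")
    return "\n".join(lines) + "\n"


def read_dataset(path, strict: bool = True):
    """Load and validate a semi-competing risks CSV.

    Returns ``(DataFrame, report)`` where ``report`` lists ``(row, message)``
    invariant violations.  In strict mode any violation raises; in lenient
    mode offending rows are dropped.
    """
    df = pd.read_csv(path, comment="#")
    report = validate_records(df)
    if report:
        if strict:
            lines = "; ".join(f"row {i}: {m}" for i, m in report[:20])
            raise ValueError(f"validation failed ({len(report)} violations): {lines}")
        bad = sorted({i for i, _ in report})
        df = df.drop(df.index[bad]).reset_index(drop=True)
    return df, report


def write_dataset(df: pd.DataFrame, path, seed: Optional[int] = None, config=None):
    """Write a dataset CSV with a reproducibility comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_comment_header(seed, config))
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# fit serialization


def _spec_to_dict(spec: ModelSpec) -> dict:
    return dict(
        baselines=[asdict(b) for b in spec.baselines],
        covariates=[list(c) for c in spec.covariates],
        lambda3_clock=spec.lambda3_clock,
        frailty=spec.frailty,
        time_scale=spec.time_scale,
    )


def _spec_from_dict(d: dict) -> ModelSpec:
    baselines = tuple(
        BaselineSpec(
            family=b["family"],
            degree=b["degree"],
            n_interior=b["n_interior"],
            boundary_knots=tuple(b["boundary_knots"]) if b["boundary_knots"] else None,
            interior_knots=tuple(b["interior_knots"])
            if b["interior_knots"] is not None
            else None,
        )
        for b in d["baselines"]
    )
    return ModelSpec(
        baselines=baselines,
        covariates=tuple(tuple(c) for c in d["covariates"]),
        lambda3_clock=d["lambda3_clock"],
        frailty=d["frailty"],
        time_scale=d["time_scale"],
    )


def fit_to_dict(fit: FitResult) -> dict:
    return dict(
        version=__version__,
        phi=fit.phi.tolist(),
        parameter_names=fit.parameter_names,
        covariance=None if fit.covariance is None else fit.covariance.tolist(),
        loglik=fit.loglik,
        converged=fit.converged,
        n=fit.n,
        n_iter=fit.n_iter,
        grad_norm=fit.grad_norm,
        message=fit.message,
        spec=_spec_to_dict(fit.spec),
    )


def fit_from_dict(d: dict) -> FitResult:
    return FitResult(
        phi=np.asarray(d["phi"], dtype=float),
        parameter_names=list(d["parameter_names"]),
        covariance=None
        if d["covariance"] is None
        else np.asarray(d["covariance"], dtype=float),
        loglik=float(d["loglik"]),
        converged=bool(d["converged"]),
        spec=_spec_from_dict(d["spec"]),
        n=int(d["n"]),
        n_iter=int(d["n_iter"]),
        grad_norm=float(d["grad_norm"]),
        message=d.get("message", ""),
    )


def write_fit_json(fit: FitResult, path):
    with open(path, "w") as fh:
        json.dump(fit_to_dict(fit), fh, indent=1)


def read_fit_json(path) -> FitResult:
    with open(path) as fh:
        return fit_from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# study outputs

SUMMARY_COLUMNS = [
    "parameter",
    "truth",
    "mean_est",
    "mean_se_a",
    "se_e",
    "coverage",
    "n_converged",
]


def write_study_outputs(result: StudyResult, prefix, seed: Optional[int] = None):
    """Write ``estimates.csv`` (archive), ``summary.csv`` and ``ise.csv``."""
    prefix = Path(prefix)
    prefix.mkdir(parents=True, exist_ok=True)
    cfg = asdict(result.design)
    header = _comment_header(seed, cfg)
    with open(prefix / "estimates.csv", "w") as fh:
        fh.write(header)
        result.estimates.to_csv(fh, index=False)
    frames = []
    for name, oc in result.summaries.items():
        t = oc.table.copy()
        t.insert(0, "spec", name)
        t["n_converged"] = oc.n_converged
        frames.append(t)
    summary = pd.concat(frames, ignore_index=True)[["spec"] + SUMMARY_COLUMNS]
    with open(prefix / "summary.csv", "w") as fh:
        fh.write(header)
        summary.to_csv(fh, index=False)
    with open(prefix / "ise.csv", "w") as fh:
        fh.write(header)
        result.ise.to_csv(fh, index=False)
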