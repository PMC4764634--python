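"""Accuracy metrics and figure-level analyses for diameter models.

The headline metric is the mean absolute relative deviation

    MARD% = (100/N) * sum_i |d_obs,i - d_pred,i| / d_obs,i

the standard percent form averaging per-sample relative deviations.
Response curves sweep one process covariate with the others fixed —
the standard way to probe whether a fitted model reproduces the physical
trends (diameter rising with flow rate, falling with distance and with
collector speed).  Points outside the design ranges are computed but
flagged: interpolation-type models cannot be extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import COVARIATE_NAMES, Dataset
from .synth import DEFAULT_COVARIATE_RANGES

__all__ = ["MardReport", "ResponseCurve", "mard", "response_curve", "parity_table"]


@dataclass(frozen=True)
class MardReport:
    """MARD% plus the per-sample relative deviations it averages."""

    mard_percent: float
    n: int
    per_sample_deviation: tuple[float, ...]  # each |obs-pred|/obs * 100


@dataclass(frozen=True)
class ResponseCurve:
    """Model predictions along a sweep of one covariate."""

    varied: str
    grid: tuple[float, ...]
    fixed: dict[str, float]
    predictions: tuple[float, ...]
    model_tag: str = ""
    out_of_range: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        if len(self.grid) != len(self.predictions):
            raise ValueError("grid and predictions must have equal length")
        g = np.asarray(self.grid)
        if len(g) > 1 and not np.all(np.diff(g) > 0):
            raise ValueError("grid must be strictly increasing")


def mard(observed, predicted) -> MardReport:
    """Mean absolute relative deviation in percent, with 100/N prefactor."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: observed {obs.shape} vs predicted {pred.shape}")
    if obs.size == 0:
        raise ValueError("empty input")
    if np.any(obs == 0):
        raise ValueError("observed values must be nonzero")
    dev = np.abs(obs - pred) / np.abs(obs) * 100.0
    return MardReport(
        mard_percent=float(dev.mean()),
        n=int(obs.size),
        per_sample_deviation=tuple(float(d) for d in dev),
    )


def _predict(model, samples) -> np.ndarray:
    """Dispatch prediction over the two model families."""
    from . import ann, gmdh

    if isinstance(model, gmdh.PolynomialModel):
        return gmdh.evaluate_many(model, samples)
    if isinstance(model, ann.MlpModel):
        return ann.predict_matrix(model, samples)
    raise TypeError(f"unsupported model type {type(model).__name__}")


def response_curve(model, varied: str, grid, fixed: dict, model_tag: str = "") -> ResponseCurve:
    """Sweep one covariate over ``grid`` with the other four held at
    ``fixed`` values, evaluating ``model`` pointwise.

    ``fixed`` maps the other covariate names to values.  Grid points
    outside the design range of the varied covariate are still computed
    but marked in ``out_of_range``.
    """
    if varied not in COVARIATE_NAMES:
        raise ValueError(f"unknown covariate {varied!r}; expected one of {COVARIATE_NAMES}")
    missing = [c for c in COVARIATE_NAMES if c != varied and c not in fixed]
    if missing:
        raise ValueError(f"fixed values missing for {missing}")
    grid = np.asarray(grid, dtype=float)
    j = COVARIATE_NAMES.index(varied)
    cov = np.empty((grid.size, 5))
    for k, name in enumerate(COVARIATE_NAMES):
        cov[:, k] = grid if k == j else fixed[name]
    preds = _predict(model, cov)
    lo, hi = DEFAULT_COVARIATE_RANGES[j]
    tol = 1e-9 * (hi - lo)
    flags = tuple(bool(g < lo - tol or g > hi + tol) for g in grid)
    return ResponseCurve(
        varied=varied,
        grid=tuple(float(g) for g in grid),
        fixed={k: float(v) for k, v in fixed.items()},
        predictions=tuple(float(p) for p in preds),
        model_tag=model_tag,
        out_of_range=flags,
    )


def parity_table(model, data: Dataset) -> list[tuple[float, float]]:
    """(observed, predicted) diameter pairs in input order, for parity
    plots of model accuracy."""
    if len(data) == 0:
        raise ValueError("empty dataset")
    if not data.has_diameters:
        raise ValueError("dataset has no measured diameters")
    preds = _predict(model, data)
    return list(zip((float(d) for d in data.diameters()), (float(p) for p in preds)))
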