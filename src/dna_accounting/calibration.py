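"""Weighted least-squares calibration of measured against expected copies.

Reference samples of known purity give pairs (ce, cm): copies forecast from
template mass versus copies counted by ddPCR.  Measurement error in this
pipeline is dominated by multiplicative sources (pipetting, fluorometric
quantification), so the residual spread grows with the copy number.  The
calibration therefore fits

    cm = a + b * ce + eps,   Var(eps) = sigma^2 * ce^gamma

by weighted least squares with weights 1/ce^gamma.  The default gamma = 2
is a constant-coefficient-of-variation model; gamma can be set by the user
or estimated empirically from the residuals of a first-pass fit.

A fitted model yields, at any ce, a two-sided prediction interval

    yhat(ce) +/- t_{1-alpha/2, dof} * sqrt(sigma^2 * ce^gamma + Var(yhat(ce)))

within which a stated fraction (default 95%) of future observations on pure
material is expected to fall.  No explicit physical variance model is
claimed; the interval is approximate by construction.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence, Union

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CalibrationPoint",
    "CalibrationModel",
    "PredictionInterval",
    "fit_calibration",
    "estimate_variance_power",
    "prediction_interval",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class CalibrationPoint:
    """One reference observation: expected copies ce (> 0) vs measured cm."""

    ce: float
    cm: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not (self.ce > 0) or not math.isfinite(self.ce):
            raise ValueError(f"ce must be finite and > 0, got {self.ce}")
        if self.cm < 0 or not math.isfinite(self.cm):
            raise ValueError(f"cm must be finite and >= 0, got {self.cm}")


@dataclass(frozen=True)
class CalibrationModel:
    """A fitted WLS calibration line with its variance model.

    ``coefficient_covariance`` is always stored as a 2x2 matrix ordered
    (intercept, slope); for a through-origin fit the intercept row/column
    is zero.
    """

    intercept: float
    slope: float
    variance_power: float
    sigma2: float
    dof: int
    coefficient_covariance: np.ndarray
    n_points: int
    level: float = 0.95
    through_origin: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cov = np.asarray(self.coefficient_covariance, dtype=float)
        if cov.shape != (2, 2):
            raise ValueError("coefficient_covariance must be 2x2")
        object.__setattr__(self, "coefficient_covariance", cov)
        if self.dof <= 0:
            raise ValueError("degrees of freedom must be > 0")
        if not (self.sigma2 >= 0):
            raise ValueError("sigma2 must be >= 0")
        if not (0 < self.level < 1):
            raise ValueError("level must be in (0, 1)")

    def predict(self, ce: float) -> float:
        """Fitted mean response at expected copies ``ce``."""
        return self.intercept + self.slope * ce


class PredictionInterval(NamedTuple):
    """Prediction bounds at one ce; ``clamped`` marks a lower bound that had
    to be raised above zero (sample is below the quantification range)."""

    lower: float
    upper: float
    clamped: bool = False


def fit_calibration(
    points: Sequence[CalibrationPoint],
    variance_power: float = 2.0,
    through_origin: bool = False,
    level: float = 0.95,
) -> CalibrationModel:
    """Fit cm = a + b*ce by WLS with weights 1/ce**variance_power.

    At least 3 points are required (5+ recommended); a warning is issued if
    the ce values span less than one order of magnitude, since the variance
    power is then poorly identified.
    """
    n = len(points)
    min_points = 2 if through_origin else 3
    if n < min_points:
        raise ValueError(f"need at least {min_points} calibration points, got {n}")
    ce = np.array([p.ce for p in points], dtype=float)
    cm = np.array([p.cm for p in points], dtype=float)
    if np.ptp(ce) == 0:
        raise ValueError("all ce values identical: calibration design is rank deficient")
    if n < 5 or ce.max() / ce.min() < 10:
        warnings.warn(
            "calibration points span less than one order of magnitude in ce "
            "(or fewer than 5 points); the fit may be unstable",
            stacklevel=2,
        )
    weights = ce ** (-variance_power)
    exog = ce[:, None] if through_origin else sm.add_constant(ce)
    res = sm.WLS(cm, exog, weights=weights).fit()

    cov = np.zeros((2, 2))
    if through_origin:
        intercept, slope = 0.0, float(res.params[0])
        cov[1, 1] = float(res.cov_params()[0, 0])
    else:
        intercept, slope = float(res.params[0]), float(res.params[1])
        cov[:, :] = np.asarray(res.cov_params())
    return CalibrationModel(
        intercept=intercept,
        slope=slope,
        variance_power=float(variance_power),
        sigma2=float(res.scale),
        dof=int(res.df_resid),
        coefficient_covariance=cov,
        n_points=n,
        level=level,
        through_origin=through_origin,
    )


def estimate_variance_power(
    points: Sequence[CalibrationPoint], through_origin: bool = False
) -> float:
    """Empirical variance power: regress log squared OLS residuals on log ce.

    A two-stage estimate of gamma in Var(eps) = sigma^2 * ce^gamma; useful
    as a check on the default constant-CV assumption (gamma = 2).
    """
    base = fit_calibration(points, variance_power=0.0, through_origin=through_origin)
    ce = np.array([p.ce for p in points], dtype=float)
    cm = np.array([p.cm for p in points], dtype=float)
    resid2 = (cm - (base.intercept + base.slope * ce)) ** 2
    resid2 = np.maximum(resid2, np.finfo(float).tiny)
    gamma = sm.OLS(np.log(resid2), sm.add_constant(np.log(ce))).fit().params[1]
    return float(gamma)


def prediction_interval(
    model: CalibrationModel, ce: float, level: float | None = None
) -> PredictionInterval:
    """Two-sided prediction interval for a new pure observation at ``ce``.

    The variance of a future observation is the modelled observation
    variance sigma^2 * ce^gamma plus the variance of the fitted mean
    x' Cov(a, b) x; the quantile is Student-t with the fit's residual
    degrees of freedom.  A non-positive lower bound is clamped to a
    machine-epsilon-scaled positive value and flagged, because the purity
    statistic divides by it.
    """
    if not (ce > 0):
        raise ValueError(f"ce must be > 0, got {ce}")
    lvl = model.level if level is None else level
    if not (0 < lvl < 1):
        raise ValueError("level must be in (0, 1)")
    x = np.array([1.0, ce])
    var_mean = float(x @ model.coefficient_covariance @ x)
    var_obs = model.sigma2 * ce**model.variance_power
    half = stats.t.ppf(0.5 + lvl / 2.0, model.dof) * math.sqrt(var_obs + var_mean)
    yhat = model.predict(ce)
    lower, upper = yhat - half, yhat + half
    clamped = lower <= 0.0
    if clamped:
        lower = np.finfo(float).eps * max(abs(yhat), 1.0)
    return PredictionInterval(lower=lower, upper=upper, clamped=clamped)


def _file_sha256(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def save_model(model: CalibrationModel, path: Union[str, Path]) -> None:
    """Serialize a fitted model to a JSON text file."""
    payload = {
        "format": "dna-accounting calibration model v1",
        "intercept": model.intercept,
        "slope": model.slope,
        "variance_power": model.variance_power,
        "sigma2": model.sigma2,
        "dof": model.dof,
        "coefficient_covariance": model.coefficient_covariance.tolist(),
        "n_points": model.n_points,
        "level": model.level,
        "through_origin": model.through_origin,
        "provenance": model.provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_model(path: Union[str, Path]) -> CalibrationModel:
    """Load a model written by :func:`save_model`."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "dna-accounting calibration model v1":
        raise ValueError(f"{path}: not a calibration model file")
    return CalibrationModel(
        intercept=payload["intercept"],
        slope=payload["slope"],
        variance_power=payload["variance_power"],
        sigma2=payload["sigma2"],
        dof=payload["dof"],
        coefficient_covariance=np.array(payload["coefficient_covariance"]),
        n_points=payload["n_points"],
        level=payload["level"],
        through_origin=payload["through_origin"],
        provenance=payload.get("provenance", {}),
    )
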