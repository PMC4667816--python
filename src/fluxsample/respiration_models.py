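"""Empirical soil-respiration response models and nonlinear least-squares fitting.

Three classic single-collar models relate chamber-measured soil respiration R
(μmol CO2 m⁻² s⁻¹) to soil temperature T (°C) and volumetric water content
W (%):

* ``R:T``    exponential temperature response  R = α·e^(β·T)
* ``R:W``    power-law moisture response       R = α·W^β
* ``R:T&W``  interactive power law             R = α·T^β·W^γ

Coefficients are estimated by nonlinear least squares on the original
(untransformed) scale, started from the closed-form log-linear regression so
that no arbitrary initial guess is needed.  Goodness of fit is the ordinary
R² = 1 − SS_res/SS_tot on the untransformed scale (negative values are
possible for pathological fits and are kept).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .io_model import CampaignTable, NumericalError, ValidationError

__all__ = [
    "ModelSpec",
    "ModelFit",
    "FitError",
    "DegenerateDataError",
    "fit_model",
    "fit_campaign",
    "predict",
    "average_r2",
    "write_fits",
]

#: relative SS_res convergence tolerance and iteration cap of the NLS solver
FTOL = 1e-10
MAX_ITER = 500


class FitError(NumericalError):
    """NLS did not converge; carries starting values and iteration count."""

    def __init__(self, message: str, initial: tuple, n_iter: int):
        super().__init__(f"{message} (initial values {initial}, {n_iter} iterations)")
        self.initial = initial
        self.n_iter = n_iter


class DegenerateDataError(ValidationError):
    """Constant response (SS_tot = 0): R² is undefined."""


class ModelSpec(str, enum.Enum):
    """Identifier of one of the three empirical response models."""

    RT = "R:T"
    RW = "R:W"
    RTW = "R:T&W"

    @classmethod
    def parse(cls, label: str) -> "ModelSpec":
        key = label.strip().upper().replace("&", "").replace(":", "").replace("_", "")
        try:
            return {"RT": cls.RT, "RW": cls.RW, "RTW": cls.RTW}[key]
        except KeyError:
            raise ValidationError(
                f"unknown model {label!r}; expected one of R:T, R:W, R:T&W"
            ) from None

    @property
    def uses_T(self) -> bool:
        return self in (ModelSpec.RT, ModelSpec.RTW)

    @property
    def uses_W(self) -> bool:
        return self in (ModelSpec.RW, ModelSpec.RTW)


@dataclass(frozen=True)
class ModelFit:
    """Fitted coefficients of one model at one collar.

    ``alpha`` is the scale (μmol m⁻² s⁻¹); ``beta`` is per-°C for R:T and a
    dimensionless exponent otherwise; ``gamma`` is present iff the model is
    R:T&W.
    """

    model: ModelSpec
    alpha: float
    beta: float
    gamma: float | None = None
    r_squared: float = math.nan
    n_obs: int = 0
    collar_id: str | None = None

    def __post_init__(self):
        if (self.model is ModelSpec.RTW) != (self.gamma is not None):
            raise ValidationError("gamma must be present iff model is R:T&W")

    @property
    def coefficients(self) -> tuple[float, ...]:
        if self.model is ModelSpec.RTW:
            return (self.alpha, self.beta, self.gamma)
        return (self.alpha, self.beta)


def _as_arrays(observations) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Accept (R, T, W) triples or a PointRecord-like with .observations."""
    if hasattr(observations, "observations"):
        observations = [(o.R, o.T, o.W) for o in observations.observations]
    arr = np.asarray(list(observations), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValidationError("observations must be (R, T, W) triples")
    keep = ~np.isnan(arr).any(axis=1)
    arr = arr[keep]
    return arr[:, 0], arr[:, 1], arr[:, 2]


def _model_functions(model: ModelSpec):
    if model is ModelSpec.RT:
        return lambda p, T, W: p[0] * np.exp(p[1] * T)
    if model is ModelSpec.RW:
        return lambda p, T, W: p[0] * np.power(W, p[1])
    return lambda p, T, W: p[0] * np.power(T, p[1]) * np.power(W, p[2])


def _log_linear_start(model: ModelSpec, R, T, W) -> np.ndarray:
    """Closed-form starting values from ordinary least squares on log scale."""
    y = np.log(R)
    if model is ModelSpec.RT:
        X = np.column_stack([np.ones_like(T), T])
    elif model is ModelSpec.RW:
        X = np.column_stack([np.ones_like(W), np.log(W)])
    else:
        X = np.column_stack([np.ones_like(T), np.log(T), np.log(W)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    coef[0] = np.exp(coef[0])
    return coef


def fit_model(observations, model: ModelSpec | str) -> ModelFit:
    """Fit one response model to a collar's (R, T, W) observations.

    Minimises Σ(R_obs − R_pred)² on the original scale with a trust-region
    least-squares solver started at the log-linear regression estimate.
    Requires ≥3 observations with R > 0 (for the log start), W > 0 for the
    moisture models and T > 0 for R:T&W.
    """
    model = ModelSpec.parse(model) if not isinstance(model, ModelSpec) else model
    R, T, W = _as_arrays(observations)
    collar_id = getattr(observations, "collar_id", None)
    if R.size < 3:
        raise ValidationError(f"need >= 3 observations, got {R.size}")
    if np.any(R <= 0):
        raise ValidationError("R must be > 0 for log-scale initialization")
    if model.uses_W and np.any(W <= 0):
        raise ValidationError(f"{model.value}: W must be > 0")
    if model is ModelSpec.RTW and np.any(T <= 0):
        raise ValidationError("R:T&W: T must be > 0 (power of T undefined)")

    ss_tot = float(np.sum((R - R.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateDataError("constant R: SS_tot = 0, R² undefined")

    f = _model_functions(model)
    p0 = _log_linear_start(model, R, T, W)

    result = least_squares(
        lambda p: f(p, T, W) - R,
        p0,
        method="lm" if R.size > p0.size else "trf",
        ftol=FTOL,
        xtol=FTOL,
        gtol=FTOL,
        max_nfev=MAX_ITER * (p0.size + 1),
    )
    if not result.success or not np.all(np.isfinite(result.x)):
        raise FitError(f"{model.value} fit failed: {result.message}",
                       tuple(p0), int(result.nfev))

    ss_res = float(np.sum(result.fun ** 2))
    # never accept a "refined" optimum worse than the closed-form start
    ss_start = float(np.sum((f(p0, T, W) - R) ** 2))
    params = result.x if ss_res <= ss_start else p0
    ss_res = min(ss_res, ss_start)

    alpha, beta = float(params[0]), float(params[1])
    gamma = float(params[2]) if model is ModelSpec.RTW else None
    return ModelFit(
        model=model,
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        r_squared=1.0 - ss_res / ss_tot,
        n_obs=int(R.size),
        collar_id=collar_id,
    )


def fit_campaign(table: CampaignTable, model: ModelSpec | str) -> dict[str, ModelFit]:
    """Fit one model independently at every collar of a campaign."""
    return {p.collar_id: fit_model(p, model) for p in table.points}


def predict(fit: ModelFit, T=None, W=None):
    """Evaluate a fitted model at driver values (scalar or array)."""
    if fit.model.uses_T and T is None:
        raise ValidationError(f"{fit.model.value} requires T")
    if fit.model.uses_W and W is None:
        raise ValidationError(f"{fit.model.value} requires W")
    if fit.model is ModelSpec.RT:
        return fit.alpha * np.exp(fit.beta * np.asarray(T, dtype=float))
    if fit.model is ModelSpec.RW:
        return fit.alpha * np.power(np.asarray(W, dtype=float), fit.beta)
    return (
        fit.alpha
        * np.power(np.asarray(T, dtype=float), fit.beta)
        * np.power(np.asarray(W, dtype=float), fit.gamma)
    )


def average_r2(fits: Iterable[ModelFit]) -> tuple[float, float]:
    """Mean R² across collars and its standard error (sd/√n).

    All fits must be of the same model; this is the per-model summary used to
    rank the three response models on a campaign.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ValidationError("need >= 2 fits to average R²")
    models = {f.model for f in fits}
    if len(models) != 1:
        raise ValidationError(f"mixed models in input: {sorted(m.value for m in models)}")
    r2 = np.array([f.r_squared for f in fits], dtype=float)
    return float(r2.mean()), float(r2.std(ddof=1) / math.sqrt(len(fits)))


def write_fits(fits: Mapping[str, ModelFit] | Sequence[ModelFit], path) -> None:
    """Write fit results to CSV: collar_id, model, alpha, beta, gamma, r_squared, n_obs."""
    if isinstance(fits, Mapping):
        items = [(cid, f) for cid, f in fits.items()]
    else:
        items = [(f.collar_id, f) for f in fits]
    pd.DataFrame(
        [
            {
                "collar_id": cid,
                "model": f.model.value,
                "alpha": f.alpha,
                "beta": f.beta,
                "gamma": "" if f.gamma is None else f.gamma,
                "r_squared": f.r_squared,
                "n_obs": f.n_obs,
            }
            for cid, f in items
        ]
    ).to_csv(path, index=False)
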