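"""First-order (total-derivative) propagation of driver errors into flux error.

Each response model maps estimation errors in its drivers into a relative
error of the predicted respiration by its total derivative:

* exponential R:T       ΔR/R = β·ΔT            (ΔT absolute, °C)
* power-law R:W         ΔR/R = β·(ΔW/W)
* interactive R:T&W     ΔR/R = β·(ΔT/T) + γ·(ΔW/W)

The exponential form is genuinely dimensionally different: its sensitivity
to temperature is β per °C, so it takes the *absolute* ΔT while the power
laws take relative errors.  The interactive form sums its two terms,
implicitly treating the T and W errors as independent.  When driven from a
Monte Carlo CV curve, the convention is ΔW/W = CV_k/100 and, for the
exponential model, ΔT = (CV_k/100)·T̄.

``linearization_check`` compares each formula with the exact relative change
of the fitted model under the same perturbation; the discrepancy decays
quadratically as the perturbation shrinks, which is the delta-method
guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from .io_model import ValidationError
from .respiration_models import ModelFit, ModelSpec, predict

__all__ = [
    "PropagatedError",
    "LinearizationCheck",
    "propagate",
    "propagate_from_cv",
    "linearization_check",
]


@dataclass(frozen=True)
class PropagatedError:
    """Relative flux error ΔR/R implied by driver errors under one model."""

    model: ModelSpec
    delta_T: float | None       # absolute, °C (exponential model)
    delta_T_rel: float | None   # ΔT/T (interactive model)
    delta_W_rel: float | None   # ΔW/W
    result: float               # ΔR/R, dimensionless


class LinearizationCheck(NamedTuple):
    exact: float        # predict(T+ΔT, W+ΔW)/predict(T, W) − 1
    linearized: float   # first-order formula
    discrepancy: float  # |exact − linearized|


def propagate(
    fit: ModelFit,
    delta_T: float | None = None,
    delta_W_rel: float | None = None,
    T_bar: float | None = None,
    W_bar: float | None = None,
) -> PropagatedError:
    """First-order ΔR/R for the given driver errors.

    ``delta_T`` is the absolute temperature error in °C; ``delta_W_rel`` is
    the relative moisture error ΔW/W.  The interactive model additionally
    needs the operating point ``T_bar`` (> 0) to form ΔT/T.
    """
    model = fit.model
    if model is ModelSpec.RT:
        if delta_T is None:
            raise ValidationError("R:T propagation requires delta_T (°C)")
        return PropagatedError(model, delta_T, None, None, fit.beta * delta_T)
    if model is ModelSpec.RW:
        if delta_W_rel is None:
            raise ValidationError("R:W propagation requires delta_W_rel")
        return PropagatedError(model, None, None, delta_W_rel, fit.beta * delta_W_rel)
    # interactive model
    if fit.gamma is None:
        raise ValidationError("R:T&W propagation requires gamma")
    if delta_T is None or delta_W_rel is None:
        raise ValidationError("R:T&W propagation requires delta_T and delta_W_rel")
    if T_bar is None or T_bar <= 0:
        raise ValidationError("R:T&W propagation requires T_bar > 0")
    delta_T_rel = delta_T / T_bar
    result = fit.beta * delta_T_rel + fit.gamma * delta_W_rel
    return PropagatedError(model, delta_T, delta_T_rel, delta_W_rel, result)


def propagate_from_cv(
    fit: ModelFit,
    cv_T: float | None = None,
    cv_W: float | None = None,
    T_bar: float | None = None,
    W_bar: float | None = None,
) -> PropagatedError:
    """Drive the propagation from CV-curve values (in percent).

    Maps CVs to driver errors as ΔW/W = cv_W/100 and ΔT = (cv_T/100)·T̄,
    so the exponential model needs ``T_bar`` to form its absolute ΔT.
    """
    delta_T = None
    if cv_T is not None:
        if T_bar is None:
            raise ValidationError("converting cv_T to ΔT requires T_bar")
        delta_T = (cv_T / 100.0) * T_bar
    delta_W_rel = None if cv_W is None else cv_W / 100.0
    return propagate(fit, delta_T=delta_T, delta_W_rel=delta_W_rel,
                     T_bar=T_bar, W_bar=W_bar)


def linearization_check(
    fit: ModelFit,
    delta_T: float | None = None,
    delta_W_rel: float | None = None,
    T_bar: float | None = None,
    W_bar: float | None = None,
) -> LinearizationCheck:
    """Exact vs first-order relative change of the model under a perturbation.

    The exact change is predict(T̄+ΔT, W̄+ΔW)/predict(T̄, W̄) − 1 with
    ΔW = (ΔW/W)·W̄; the linearized change comes from :func:`propagate`.
    """
    model = fit.model
    dT = delta_T or 0.0
    dW_rel = delta_W_rel or 0.0
    if model.uses_T and T_bar is None:
        raise ValidationError(f"{model.value} check requires T_bar")
    if model.uses_W and W_bar is None:
        raise ValidationError(f"{model.value} check requires W_bar")
    base = float(predict(fit, T=T_bar, W=W_bar))
    if base == 0:
        raise ValidationError("baseline prediction is zero")
    T_pert = None if T_bar is None else T_bar + dT
    W_pert = None if W_bar is None else W_bar * (1.0 + dW_rel)
    exact = float(predict(fit, T=T_pert, W=W_pert)) / base - 1.0
    linear = propagate(
        fit,
        delta_T=delta_T if model.uses_T else None,
        delta_W_rel=delta_W_rel if model.uses_W else None,
        T_bar=T_bar,
        W_bar=W_bar,
    ).result
    return LinearizationCheck(exact, linear, abs(exact - linear))
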