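"""Growing-season flux integration and the representative diurnal window.

The seasonal CO2 emission at a collar is obtained by driving its fitted
respiration model with the continuous 30-min T/W logger series and
integrating the predicted efflux over the growing season (default
16 June – 19 September) with the trapezoidal rule.  Units: the instantaneous
efflux is μmol CO2 m⁻² s⁻¹, so the time integral in seconds × 1e-6 gives
mol CO2 m⁻², converted to g C m⁻² with 12.011 g C per mol CO2 (and to
g CO2 m⁻² with 44.01 g per mol).

The representative diurnal window is the part of the day during which the
instantaneous efflux stays within a tolerance band (default ±10%) of the
daily mean — the basis for choosing a once-daily chamber measurement time
that approximates the daily average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import ContinuousSeries, ValidationError
from .respiration_models import ModelFit, ModelSpec, predict

__all__ = [
    "GRAMS_C_PER_MOL_CO2",
    "GRAMS_CO2_PER_MOL",
    "CoverageError",
    "RangeError",
    "EmissionEstimate",
    "DiurnalWindow",
    "default_season",
    "integrate_emission",
    "representative_window",
]

GRAMS_C_PER_MOL_CO2 = 12.011   # carbon mass per mol CO2
GRAMS_CO2_PER_MOL = 44.01      # CO2 mass per mol

#: largest tolerated logger gap; shorter gaps are bridged by linear
#: interpolation of the drivers (T, W), never of the flux itself
MAX_GAP = pd.Timedelta(hours=24)


class CoverageError(ValidationError):
    """The driver series has a gap too large to interpolate across."""


class RangeError(ValidationError):
    """The requested window lies (partly) outside the series span."""


def default_season(year: int) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Default integration window: 16 June 00:00 through 19 September 24:00."""
    return pd.Timestamp(year=year, month=6, day=16), pd.Timestamp(year=year, month=9, day=20)


@dataclass(frozen=True)
class EmissionEstimate:
    """Seasonal CO2 emission at one collar under one response model."""

    collar_id: str | None
    model: ModelSpec
    window: tuple[pd.Timestamp, pd.Timestamp]
    total_mol: float    # mol CO2 m⁻²
    total_gC: float     # g C m⁻²
    total_gCO2: float   # g CO2 m⁻²


@dataclass(frozen=True)
class DiurnalWindow:
    """Time-of-day intervals where efflux tracks the daily mean.

    ``intervals`` are half-open [start, end) in decimal hours (0–24); a
    constant series yields the single interval (0.0, 24.0).
    """

    intervals: list[tuple[float, float]]
    tolerance: float
    daily_mean: float

    @property
    def total_hours(self) -> float:
        return sum(e - s for s, e in self.intervals)


def integrate_emission(
    fit: ModelFit,
    series: ContinuousSeries,
    window: tuple | None = None,
) -> EmissionEstimate:
    """Trapezoidal integral of the modelled efflux over a date window.

    The model is evaluated at every 30-min grid point of the driver series
    inside the window.  Gaps up to 24 h in the loggers are bridged by linear
    interpolation of T and W on the 30-min grid (the flux is a nonlinear map
    of the drivers, so interpolating R itself would bias the integral);
    larger gaps raise :class:`CoverageError`.  A window outside the series
    span raises :class:`RangeError`; a zero-length window integrates to 0.
    """
    if window is None:
        window = default_season(int(series.timestamps[0].year))
    start, end = (pd.Timestamp(window[0]), pd.Timestamp(window[1]))
    if end < start:
        raise ValidationError(f"window end {end} before start {start}")
    if start == end:
        return EmissionEstimate(series.collar_id, fit.model, (start, end), 0.0, 0.0, 0.0)
    if start < series.timestamps[0] or end > series.timestamps[-1]:
        raise RangeError(
            f"window [{start}, {end}] outside series span "
            f"[{series.timestamps[0]}, {series.timestamps[-1]}]"
        )

    frame = series.frame().loc[start:end]
    if len(frame) < 2:
        raise CoverageError("fewer than 2 driver records inside the window")
    gaps = frame.index.to_series().diff().dropna()
    if (gaps > MAX_GAP).any():
        worst = gaps.max()
        raise CoverageError(
            f"driver gap of {worst} inside the window exceeds {MAX_GAP}"
        )
    # regularise to the 30-min grid and bridge short gaps in the drivers
    grid = pd.date_range(frame.index[0], frame.index[-1], freq=ContinuousSeries.CADENCE)
    frame = frame.reindex(frame.index.union(grid)).interpolate(method="time").loc[grid]

    flux = np.asarray(
        predict(fit, T=frame["T"].to_numpy(), W=frame["W"].to_numpy()), dtype=float
    )
    if not np.all(np.isfinite(flux)):
        raise ValidationError("model prediction not finite over the series")
    seconds = (grid - grid[0]).total_seconds().to_numpy()
    micromol = float(np.trapezoid(flux, seconds))  # μmol m⁻²
    total_mol = micromol * 1e-6
    return EmissionEstimate(
        collar_id=series.collar_id,
        model=fit.model,
        window=(start, end),
        total_mol=total_mol,
        total_gC=total_mol * GRAMS_C_PER_MOL_CO2,
        total_gCO2=total_mol * GRAMS_CO2_PER_MOL,
    )


def representative_window(diurnal: pd.Series, tolerance: float = 0.10) -> DiurnalWindow:
    """Time-of-day band where the mean diurnal efflux stays near its daily mean.

    ``diurnal`` is an efflux series (μmol m⁻² s⁻¹) indexed by timestamps at a
    uniform cadence spanning at least one whole day.  The mean diurnal cycle
    is formed by averaging across days at each time of day; the result lists
    the maximal time-of-day intervals (wrapping midnight) on which
    ``|cycle − mean| ≤ tolerance × mean``.
    """
    if not isinstance(diurnal, pd.Series):
        raise ValidationError("diurnal must be a pandas Series indexed by timestamps")
    if len(diurnal) < 2:
        raise CoverageError("diurnal series too short")
    idx = pd.DatetimeIndex(diurnal.index)
    steps = np.diff(idx.values).astype("timedelta64[s]").astype(float)
    step = steps[0]
    if step <= 0 or not np.allclose(steps, step, rtol=0, atol=1.0):
        raise ValidationError("diurnal series must have uniform cadence")
    per_day = round(86400.0 / step)
    if abs(per_day * step - 86400.0) > 1.0:
        raise ValidationError("cadence must divide 24 h evenly")
    if len(diurnal) < per_day:
        raise CoverageError(
            f"need at least one full day ({per_day} samples at {step:.0f} s), "
            f"got {len(diurnal)}"
        )

    seconds_of_day = idx.hour * 3600 + idx.minute * 60 + idx.second
    slot = (seconds_of_day.to_numpy() / step).round().astype(int) % per_day
    cycle = pd.Series(diurnal.to_numpy(), dtype=float).groupby(slot).mean()
    cycle = cycle.reindex(range(per_day))
    if cycle.isna().any():
        raise CoverageError("diurnal cycle has uncovered times of day")
    values = cycle.to_numpy()
    mean = float(values.mean())
    if mean == 0:
        raise ValidationError("daily mean is zero; band undefined")

    inside = np.abs(values - mean) <= tolerance * abs(mean)
    hours_per_slot = step / 3600.0
    if inside.all():
        return DiurnalWindow([(0.0, 24.0)], tolerance, mean)
    if not inside.any():
        return DiurnalWindow([], tolerance, mean)

    # maximal runs of in-band slots on the circular day
    intervals: list[tuple[float, float]] = []
    padded = np.concatenate([[False], inside, [False]])
    starts = np.nonzero(padded[1:].astype(int) - padded[:-1].astype(int) == 1)[0]
    ends = np.nonzero(padded[1:].astype(int) - padded[:-1].astype(int) == -1)[0]
    runs = list(zip(starts, ends))  # half-open slot ranges
    # merge a run touching midnight's end with one starting at slot 0
    if len(runs) >= 2 and runs[0][0] == 0 and runs[-1][1] == per_day:
        first, last = runs[0], runs.pop()
        runs[0] = (last[0], first[1] + per_day)
    for s, e in runs:
        intervals.append((s * hours_per_slot, e * hours_per_slot))
    intervals.sort()
    return DiurnalWindow(intervals, tolerance, mean)
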