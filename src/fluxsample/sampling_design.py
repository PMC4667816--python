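"""Optimal sample-size detection and the subplot/density design comparison.

A CV-versus-n curve falls steeply at small n and flattens as n approaches
the full collar count.  The threshold rule declares the *optimal sample
size* n* as the smallest n at which the discrete slope dCV/dn rises above
−1.0 (% per collar): below the threshold an extra collar still buys more
than one percentage point of precision, above it the gain is marginal.  The
slope is the forward difference s_n = CV_{n+1} − CV_n assigned to n; a tie
(s_n exactly −1.0) does not exceed the threshold.  If every slope stays
below the threshold the optimum is *not obtained* — the plot's collar count
is too small to flatten the curve.

``design_table`` repeats the whole analysis (per-collar means → Monte Carlo
CV curves → threshold rule) over the full plot and a set of subplot
partitions with different point densities, producing one row per plot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import (
    CampaignTable,
    ContinuousSeries,
    ValidationError,
    subplot_area_km2,
    subset_points,
    summarize_point,
)
from .mc_subsampling import DEFAULT_M, CVCurve, SizeError, mc_cv_curve
from .respiration_models import ModelFit, ModelSpec, fit_model
from .seasonal_flux import integrate_emission

__all__ = [
    "DEFAULT_THRESHOLD",
    "OptimalSize",
    "DesignTable",
    "optimal_sample_size",
    "collar_values",
    "design_table",
]

#: threshold on the discrete slope dCV/dn, in % per collar
DEFAULT_THRESHOLD = -1.0


@dataclass(frozen=True)
class OptimalSize:
    """Result of the threshold rule on one CV curve.

    ``n_star`` is None when the optimum was not obtained (every slope below
    the threshold).  ``slope_table`` maps n to the forward slope s_n.
    """

    n_star: int | None
    cv_at_n_star: float | None
    threshold: float
    slope_table: dict[int, float]

    @property
    def obtained(self) -> bool:
        return self.n_star is not None

    def __str__(self) -> str:
        if not self.obtained:
            return "not obtained"
        return f"n*={self.n_star} (CV {self.cv_at_n_star:.1f}%)"


def optimal_sample_size(
    curve: CVCurve | Mapping[int, float],
    threshold: float = DEFAULT_THRESHOLD,
) -> OptimalSize:
    """Apply the dCV/dn threshold rule to a CV curve.

    Accepts a :class:`CVCurve` or a plain mapping n → CV(%).  Slopes are
    forward differences over consecutive n present in the curve; n* is the
    smallest n with s_n strictly above the threshold.
    """
    cv = dict(curve.cv_by_k) if isinstance(curve, CVCurve) else dict(curve)
    ns = sorted(cv)
    if len(ns) < 2:
        raise SizeError("CV curve needs at least 2 points")
    if ns != list(range(ns[0], ns[-1] + 1)):
        raise ValidationError("CV curve must cover consecutive sample sizes")
    slopes = {n: cv[n + 1] - cv[n] for n in ns[:-1]}
    for n in ns[:-1]:
        if slopes[n] > threshold:
            return OptimalSize(
                n_star=n,
                cv_at_n_star=cv[n],
                threshold=threshold,
                slope_table=slopes,
            )
    return OptimalSize(n_star=None, cv_at_n_star=None, threshold=threshold,
                       slope_table=slopes)


@dataclass
class DesignTable:
    """One row per analysed plot: counts, densities, and per-variable optima."""

    rows: list[dict]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def collar_values(
    campaign: CampaignTable,
    continuous: Mapping[str, ContinuousSeries],
    models: Sequence[ModelSpec | str] = (ModelSpec.RT, ModelSpec.RW, ModelSpec.RTW),
    window: tuple | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, dict[str, ModelFit]]]:
    """Per-collar campaign means and per-model seasonal emissions.

    Returns ``(values, fits)`` where ``values`` maps variable label
    ("T", "W", "R:T", ...) to one number per collar (campaign order) and
    ``fits`` maps model label to the per-collar fit dictionary.
    """
    models = [ModelSpec.parse(m) if not isinstance(m, ModelSpec) else m for m in models]
    missing = [p.collar_id for p in campaign.points if p.collar_id not in continuous]
    if missing:
        raise ValidationError(f"collars without continuous data: {missing[:5]}")

    mean_T, mean_W = [], []
    for p in campaign.points:
        s = summarize_point(p)
        mean_T.append(s.mean_T)
        mean_W.append(s.mean_W)
    values: dict[str, np.ndarray] = {
        "T": np.asarray(mean_T, dtype=float),
        "W": np.asarray(mean_W, dtype=float),
    }
    fits: dict[str, dict[str, ModelFit]] = {}
    for model in models:
        per_collar: dict[str, ModelFit] = {}
        emissions = []
        for p in campaign.points:
            fit = fit_model(p, model)
            per_collar[p.collar_id] = fit
            est = integrate_emission(fit, continuous[p.collar_id], window=window)
            emissions.append(est.total_gC)
        fits[model.value] = per_collar
        values[model.value] = np.asarray(emissions, dtype=float)
    return values, fits


def _child_seed(seed: int | None, *key: int) -> int | None:
    """Deterministic per-task seed below 2**31 derived from the master seed."""
    if seed is None:
        return None
    ss = np.random.SeedSequence([int(seed), *key])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def design_table(
    campaign: CampaignTable,
    continuous: Mapping[str, ContinuousSeries],
    models: Sequence[ModelSpec | str] = (ModelSpec.RT, ModelSpec.RW, ModelSpec.RTW),
    M: int = DEFAULT_M,
    seed: int | None = None,
    partitions: Sequence[tuple[str, Iterable[int] | None]] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    window: tuple | None = None,
) -> tuple[DesignTable, dict[str, list[CVCurve]]]:
    """Full design comparison across plot partitions.

    ``partitions`` is a sequence of (label, subplot set) pairs; None as the
    subplot set means the full plot.  Default: the full plot plus the four
    contiguous half-plot pairings.  For each partition and each variable
    (mean T, mean W, seasonal emission per model) a Monte Carlo CV curve is
    computed and the threshold rule applied; each curve gets its own
    deterministic child seed derived from ``seed``.

    Returns the table and the CV curves keyed by partition label.
    """
    if partitions is None:
        partitions = [
            ("full plot", None),
            ("subplot 1+2", {1, 2}),
            ("subplot 2+3", {2, 3}),
            ("subplot 1+4", {1, 4}),
            ("subplot 3+4", {3, 4}),
        ]
    rows: list[dict] = []
    curves: dict[str, list[CVCurve]] = {}
    for part_index, (label, subplots) in enumerate(partitions):
        sub = campaign if subplots is None else subset_points(campaign, subplots)
        if sub.n_points < 2:
            raise SizeError(
                f"partition {label!r} has {sub.n_points} collar(s); need >= 2"
            )
        area = subplot_area_km2(campaign, subplots)
        values, _fits = collar_values(sub, continuous, models=models, window=window)
        row: dict = {
            "plot": label,
            "points": sub.n_points,
            "density_per_km2": round(sub.n_points / area, 2),
        }
        part_curves: list[CVCurve] = []
        for var_index, (variable, vals) in enumerate(values.items()):
            if np.allclose(vals.std(), 0.0):
                # perfectly homogeneous collars: CV identically 0, n* = 1
                curve = CVCurve(
                    variable=variable, N=len(vals), M=M, E_N=float(vals.mean()),
                    cv_by_k={k: 0.0 for k in range(1, len(vals))},
                    seed=_child_seed(seed, part_index, var_index),
                )
            else:
                curve = mc_cv_curve(
                    vals, M=M, seed=_child_seed(seed, part_index, var_index),
                    variable=variable,
                )
            part_curves.append(curve)
            opt = optimal_sample_size(curve, threshold=threshold)
            row[f"n_star[{variable}]"] = opt.n_star if opt.obtained else "not obtained"
            row[f"cv[{variable}]"] = (
                round(opt.cv_at_n_star, 1) if opt.obtained else ""
            )
        curves[label] = part_curves
        rows.append(row)
    return DesignTable(rows=rows), curves
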