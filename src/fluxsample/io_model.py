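"""Domain types and delimited-text I/O for collar-based soil-respiration campaigns.

The sampling unit throughout is the *collar*: a PVC ring inserted in the soil
on which a chamber system measures soil CO2 efflux (R, μmol CO2 m⁻² s⁻¹),
alongside soil temperature at 10 cm (T, °C) and volumetric soil water content
at 0–10 cm (W, %).  A campaign is a set of collars in a rectangular plot,
each visited on a series of dates; continuous loggers provide 30-min averaged
T and W per collar for seasonal integration.

Two CSV dialects are supported (header mandatory, UTF-8, "." decimal):

* campaign:   ``collar_id,x_km,y_km,subplot,date,R,T,W``
* continuous: ``collar_id,timestamp,T,W`` at 30-min cadence
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FluxSampleError",
    "ValidationError",
    "NumericalError",
    "FormatError",
    "ParseError",
    "DuplicateError",
    "EmptySelectionError",
    "EmptyDataError",
    "Observation",
    "PointRecord",
    "CampaignTable",
    "ContinuousSeries",
    "PointSummary",
    "subplot_of",
    "read_campaign",
    "write_campaign",
    "read_continuous",
    "write_continuous",
    "subset_points",
    "summarize_point",
]


# ---------------------------------------------------------------------------
# Error hierarchy (shared by all stages)
# ---------------------------------------------------------------------------

class FluxSampleError(Exception):
    """Base class for every error raised by this package."""


class ValidationError(FluxSampleError):
    """Invalid input data or arguments (CLI exit code 2)."""


class NumericalError(FluxSampleError):
    """A numerical procedure failed (CLI exit code 3)."""


class FormatError(ValidationError):
    """A file does not conform to the expected CSV dialect."""


class ParseError(ValidationError):
    """A cell could not be parsed; carries the offending row number."""


class DuplicateError(ValidationError):
    """Duplicate key, e.g. two rows for the same (collar, date)."""


class EmptySelectionError(ValidationError):
    """A subset operation selected no points."""


class EmptyDataError(ValidationError):
    """An operation received no usable observations."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class Observation(NamedTuple):
    """One dated chamber measurement at a collar.

    NaN in any of R/T/W marks a missing value for that date; missing values
    are skipped when averaging, but a collar must retain at least one valid
    observation.
    """

    date: pd.Timestamp
    R: float  # soil respiration, μmol CO2 m⁻² s⁻¹
    T: float  # soil temperature at 10 cm, °C
    W: float  # volumetric water content 0–10 cm, %


def subplot_of(x_km: float, y_km: float, extent: tuple[float, float]) -> int:
    """Quadrant label for a point: 1=SW, 2=SE, 3=NE, 4=NW (half-open split).

    The west/south half-planes are ``x < width/2`` and ``y < height/2``.
    With this labelling the four contiguous half-plot pairings are
    {1,2} south, {2,3} east, {1,4} west and {3,4} north.
    """
    w, h = extent
    east = x_km >= w / 2.0
    north = y_km >= h / 2.0
    if not north:
        return 2 if east else 1
    return 3 if east else 4


@dataclass
class PointRecord:
    """A single collar: location, subplot label and its dated observations."""

    collar_id: str
    x_km: float
    y_km: float
    subplot: int
    observations: list[Observation] = field(default_factory=list)

    def validate(self, extent: tuple[float, float] | None = None) -> None:
        if self.subplot not in (1, 2, 3, 4):
            raise ValidationError(
                f"collar {self.collar_id!r}: subplot must be 1..4, got {self.subplot}"
            )
        if extent is not None:
            expected = subplot_of(self.x_km, self.y_km, extent)
            if expected != self.subplot:
                raise ValidationError(
                    f"collar {self.collar_id!r}: subplot {self.subplot} inconsistent "
                    f"with coordinates ({self.x_km}, {self.y_km}) -> quadrant {expected}"
                )
        last = None
        n_valid = 0
        for obs in self.observations:
            if last is not None and obs.date <= last:
                raise ValidationError(
                    f"collar {self.collar_id!r}: dates not strictly increasing at {obs.date}"
                )
            last = obs.date
            if not math.isnan(obs.R):
                if not math.isfinite(obs.R) or obs.R < 0:
                    raise ValidationError(
                        f"collar {self.collar_id!r} {obs.date.date()}: R={obs.R} "
                        "must be finite and >= 0"
                    )
                n_valid += 1
            if not math.isnan(obs.W) and not (0.0 <= obs.W <= 100.0):
                raise ValidationError(
                    f"collar {self.collar_id!r} {obs.date.date()}: W={obs.W} must be "
                    "volumetric percent in [0, 100] (fractions are rejected)"
                )
        if self.observations and n_valid == 0:
            raise EmptyDataError(
                f"collar {self.collar_id!r} has no valid observations"
            )


@dataclass
class CampaignTable:
    """The full point campaign: the finite population ("sample A") of size N."""

    points: list[PointRecord]
    plot_extent: tuple[float, float] = (5.0, 5.0)  # km

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def collar_ids(self) -> list[str]:
        return [p.collar_id for p in self.points]

    def validate(self, check_coords: bool = True) -> None:
        ids = self.collar_ids
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateError(f"duplicate collar ids: {dupes}")
        for p in self.points:
            p.validate(self.plot_extent if check_coords else None)

    def point(self, collar_id: str) -> PointRecord:
        for p in self.points:
            if p.collar_id == collar_id:
                return p
        raise KeyError(collar_id)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.points:
            for obs in p.observations:
                rows.append(
                    (p.collar_id, p.x_km, p.y_km, p.subplot,
                     obs.date.date().isoformat(), obs.R, obs.T, obs.W)
                )
        return pd.DataFrame(
            rows, columns=["collar_id", "x_km", "y_km", "subplot", "date", "R", "T", "W"]
        )


@dataclass
class ContinuousSeries:
    """30-min averaged logger series of T and W at one collar."""

    collar_id: str
    timestamps: pd.DatetimeIndex
    T_series: np.ndarray
    W_series: np.ndarray

    #: nominal cadence
    CADENCE = pd.Timedelta(minutes=30)

    def validate(self, tolerance: pd.Timedelta = pd.Timedelta(minutes=1)) -> None:
        if len(self.timestamps) != len(self.T_series) or len(self.timestamps) != len(self.W_series):
            raise ValidationError(
                f"collar {self.collar_id!r}: series lengths differ"
            )
        if len(self.timestamps) >= 2:
            steps = np.diff(self.timestamps.values).astype("timedelta64[s]").astype(float)
            nominal = self.CADENCE.total_seconds()
            tol = tolerance.total_seconds()
            # gaps (missing records) are allowed here; integration enforces
            # its own coverage rule.  Only sub-nominal / ragged spacing is
            # rejected.
            if np.any(steps < nominal - tol):
                raise ValidationError(
                    f"collar {self.collar_id!r}: cadence finer than 30 min"
                )
            remainder = np.mod(steps, nominal)
            off = np.minimum(remainder, nominal - remainder)
            if np.any(off > tol):
                raise ValidationError(
                    f"collar {self.collar_id!r}: timestamps not on a 30-min grid"
                )

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"T": self.T_series, "W": self.W_series}, index=self.timestamps
        )


@dataclass
class PointSummary:
    """Per-collar campaign summary used by the Monte Carlo stage."""

    collar_id: str
    mean_T: float  # °C, arithmetic mean over campaign dates
    mean_W: float  # %, arithmetic mean over campaign dates
    emission_mol: float | None = None   # mol CO2 m⁻² over the season
    emission_gC: float | None = None    # g C m⁻² over the season


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_CAMPAIGN_COLUMNS = ["collar_id", "x_km", "y_km", "subplot", "date", "R", "T", "W"]
_CONTINUOUS_COLUMNS = ["collar_id", "timestamp", "T", "W"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")


def _numeric(df: pd.DataFrame, column: str, path, allow_nan: bool = True) -> pd.Series:
    """Parse a column to float; empty cells become NaN, garbage is an error."""
    raw = df[column]
    out = pd.to_numeric(raw, errors="coerce")
    blank = raw.isna() | (raw.astype(str).str.strip() == "")
    bad = out.isna() & ~blank
    if bad.any():
        row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ParseError(
            f"{path}: non-numeric value {raw[bad.idxmax()]!r} in column "
            f"{column!r} at line {row}"
        )
    if not allow_nan and out.isna().any():
        row = int(out.isna().idxmax()) + 2
        raise ParseError(f"{path}: missing value in column {column!r} at line {row}")
    return out.astype(float)


def read_campaign(path) -> CampaignTable:
    """Read a campaign CSV into a :class:`CampaignTable`.

    Rows are grouped by collar and sorted by date; duplicate (collar, date)
    pairs are rejected.  An empty file (header only) yields a table with
    zero points.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    _require_columns(df, _CAMPAIGN_COLUMNS, path)
    if len(df) == 0:
        return CampaignTable(points=[])
    for col in ("x_km", "y_km", "R", "T", "W"):
        df[col] = _numeric(df.assign(**{col: df[col].replace("", np.nan)}), col, path)
    df["subplot"] = _numeric(df, "subplot", path, allow_nan=False).astype(int)
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except ValueError as exc:
        raise ParseError(f"{path}: unparseable date ({exc})") from None

    if df.duplicated(subset=["collar_id", "date"]).any():
        dup = df[df.duplicated(subset=["collar_id", "date"])].iloc[0]
        raise DuplicateError(
            f"{path}: duplicate observation for collar {dup['collar_id']!r} "
            f"on {dup['date'].date()}"
        )

    points: list[PointRecord] = []
    for collar_id, grp in df.groupby("collar_id", sort=False):
        grp = grp.sort_values("date")
        first = grp.iloc[0]
        obs = [
            Observation(row.date, row.R, row.T, row.W)
            for row in grp.itertuples(index=False)
        ]
        points.append(
            PointRecord(
                collar_id=str(collar_id),
                x_km=float(first["x_km"]),
                y_km=float(first["y_km"]),
                subplot=int(first["subplot"]),
                observations=obs,
            )
        )
    table = CampaignTable(points=points)
    table.validate()
    return table


def write_campaign(table: CampaignTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_continuous(path) -> dict[str, ContinuousSeries]:
    """Read a continuous-logger CSV into per-collar series."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    _require_columns(df, _CONTINUOUS_COLUMNS, path)
    out: dict[str, ContinuousSeries] = {}
    if len(df) == 0:
        return out
    for col in ("T", "W"):
        df[col] = _numeric(df.assign(**{col: df[col].replace("", np.nan)}), col, path)
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    except ValueError as exc:
        raise ParseError(f"{path}: unparseable timestamp ({exc})") from None
    for collar_id, grp in df.groupby("collar_id", sort=False):
        grp = grp.sort_values("timestamp")
        series = ContinuousSeries(
            collar_id=str(collar_id),
            timestamps=pd.DatetimeIndex(grp["timestamp"]),
            T_series=grp["T"].to_numpy(),
            W_series=grp["W"].to_numpy(),
        )
        series.validate()
        out[str(collar_id)] = series
    return out


def write_continuous(series: Mapping[str, ContinuousSeries] | Iterable[ContinuousSeries], path) -> None:
    if isinstance(series, Mapping):
        series = series.values()
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "collar_id": s.collar_id,
                    "timestamp": s.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
                    "T": s.T_series,
                    "W": s.W_series,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Subsetting and summarisation
# ---------------------------------------------------------------------------

def subset_points(table: CampaignTable, subplots: Iterable[int]) -> CampaignTable:
    """Restrict a campaign to the collars in the given subplot labels.

    The plot extent is recomputed: a contiguous selection of quadrants keeps
    its bounding-box dimensions (e.g. the south half {1,2} of a 5×5 km plot
    is 5×2.5 km).
    """
    labels = set(int(s) for s in subplots)
    bad = labels - {1, 2, 3, 4}
    if bad:
        raise ValidationError(f"invalid subplot labels: {sorted(bad)}")
    selected = [p for p in table.points if p.subplot in labels]
    if not selected:
        raise EmptySelectionError(f"no points in subplots {sorted(labels)}")
    w, h = table.plot_extent
    xs = {1: (0, w / 2), 2: (w / 2, w), 3: (w / 2, w), 4: (0, w / 2)}
    ys = {1: (0, h / 2), 2: (0, h / 2), 3: (h / 2, h), 4: (h / 2, h)}
    x_lo = min(xs[s][0] for s in labels)
    x_hi = max(xs[s][1] for s in labels)
    y_lo = min(ys[s][0] for s in labels)
    y_hi = max(ys[s][1] for s in labels)
    return CampaignTable(points=selected, plot_extent=(x_hi - x_lo, y_hi - y_lo))


def subplot_area_km2(table: CampaignTable, subplots: Iterable[int] | None = None) -> float:
    """Area in km² covered by a set of quadrant labels (or the whole plot)."""
    w, h = table.plot_extent
    if subplots is None:
        return w * h
    labels = set(int(s) for s in subplots)
    return len(labels) * (w / 2) * (h / 2)


def summarize_point(record: PointRecord, continuous=None, fit=None,
                    window=None) -> PointSummary:
    """Average campaign T and W at a collar; optionally attach its seasonal emission.

    ``mean_T``/``mean_W`` are arithmetic means over the collar's campaign
    observations (missing values skipped).  If a fitted respiration model and
    a continuous driver series are supplied, the collar's growing-season
    emission is computed by :func:`fluxsample.seasonal_flux.integrate_emission`.
    """
    if not record.observations:
        raise EmptyDataError(f"collar {record.collar_id!r} has no observations")
    T = np.array([o.T for o in record.observations], dtype=float)
    W = np.array([o.W for o in record.observations], dtype=float)
    if np.all(np.isnan(T)) and np.all(np.isnan(W)):
        raise EmptyDataError(f"collar {record.collar_id!r} has no valid observations")
    summary = PointSummary(
        collar_id=record.collar_id,
        mean_T=float(np.nanmean(T)) if not np.all(np.isnan(T)) else math.nan,
        mean_W=float(np.nanmean(W)) if not np.all(np.isnan(W)) else math.nan,
    )
    if fit is not None and continuous is not None:
        from .seasonal_flux import integrate_emission

        est = integrate_emission(fit, continuous, window=window)
        summary.emission_mol = est.total_mol
        summary.emission_gC = est.total_gC
    return summary
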