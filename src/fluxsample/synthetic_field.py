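"""Synthetic oasis-farmland campaign generator.

Emulates a 51-collar chamber campaign on an irrigated maize plot of
5×5 km², divided into four 2.5×2.5 km² quadrant subplots holding
15/15/12/9 collars (so the four contiguous half-plot pairings contain
30/27/24/21 points).  Collars are laid out on an even grid per subplot.
Each collar carries a continuous 30-min T/W logger series over the season
and dated chamber observations every 6 days within the 8:30–12:00 morning
window.

Across-collar heterogeneity is multiplicative lognormal (positive-valued,
CV-parameterised): collar factors scale a shared seasonal temperature
sinusoid (peaking mid-July), a shared irrigation-pulse moisture sawtooth
(sharp rise at each irrigation, exponential decay — the site is arid and
its farmland irrigation-fed), and the respiration scale α of the truth
model.  Chamber R observations get multiplicative lognormal noise.  The
default spatial CVs (T ≈ 5%, W ≈ 10%, seasonal emission ≈ 11%) mirror the
site's reported magnitudes; everything is fully determined by the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_model import (
    CampaignTable,
    ContinuousSeries,
    Observation,
    PointRecord,
    ValidationError,
    subplot_of,
)
from .respiration_models import ModelFit, ModelSpec, predict

__all__ = [
    "ConfigError",
    "SyntheticConfig",
    "generate_campaign",
    "generate_diurnal",
]


class ConfigError(ValidationError):
    """Inconsistent generator configuration."""


def _lognormal_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """n multiplicative lognormal factors with mean 1 and the given CV (%)."""
    c = cv / 100.0
    if c < 0:
        raise ConfigError(f"CV must be >= 0, got {cv}")
    if c == 0:
        return np.ones(n)
    sigma2 = math.log1p(c * c)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=n)


@dataclass(frozen=True)
class SyntheticConfig:
    """Stated world of the emulated campaign; defaults mirror the site.

    Spatial CVs are across-collar CVs of the collar means, in percent.
    ``truth_model`` with (``truth_beta``, ``truth_gamma``) and ``mean_R``
    define the generating respiration response; the scale α per collar is
    ``mean_R / f(mean_T, mean_W)`` times a lognormal factor with CV
    ``cv_alpha_spatial``.  ``noise_sigma`` is the log-sd of the
    multiplicative observation noise on chamber R.
    """

    n_points: int = 51
    plot_extent: tuple[float, float] = (5.0, 5.0)          # km
    subplot_counts: tuple[int, int, int, int] = (15, 15, 12, 9)
    year: int = 2012
    season: tuple[str, str] = ("06-16", "09-19")            # integration window
    campaign_start: str = "06-06"                           # first chamber visit
    campaign_every_days: int = 6
    obs_window_hours: tuple[float, float] = (8.5, 12.0)     # 8:30–12:00
    mean_T: float = 20.0            # °C, collar-mean centre
    cv_T_spatial: float = 5.0       # %
    mean_W: float = 25.0            # volumetric %, collar-mean centre
    cv_W_spatial: float = 10.0      # %
    seasonal_T_amplitude: float = 4.0   # °C, sinusoid peaking mid-July
    diurnal_T_amplitude: float = 5.0    # °C, afternoon peak
    # 11-day cycle: deliberately incommensurate with the 6-day campaign
    # cadence so chamber visits sample the whole wet-dry phase, not two slices
    irrigation_period_days: float = 11.0
    irrigation_decay_days: float = 5.0
    truth_model: ModelSpec = ModelSpec.RTW
    truth_beta: float = 1.649
    truth_gamma: float = 0.622
    mean_R: float = 4.5             # μmol m⁻² s⁻¹ at (mean_T, mean_W)
    cv_alpha_spatial: float = 4.0   # %
    noise_sigma: float = 0.1        # lognormal log-sd on chamber R
    logger_noise_T: float = 0.2     # °C, additive on logged T
    logger_noise_W_rel: float = 0.01  # relative, on logged W
    diurnal_mean: float = 4.5       # μmol m⁻² s⁻¹ (preliminary-experiment cycle)
    diurnal_peak: float = 7.0
    diurnal_peak_hour: float = 13.5
    diurnal_peak_jitter_hours: float = 1.0
    diurnal_days: int = 5
    seed: int = 0

    def validate(self) -> None:
        if sum(self.subplot_counts) != self.n_points:
            raise ConfigError(
                f"subplot counts {self.subplot_counts} do not partition "
                f"n_points={self.n_points}"
            )
        if len(self.subplot_counts) != 4:
            raise ConfigError("exactly four subplots expected")
        for cv in (self.cv_T_spatial, self.cv_W_spatial, self.cv_alpha_spatial):
            if cv < 0:
                raise ConfigError(f"spatial CV must be >= 0, got {cv}")
        if self.diurnal_peak < self.diurnal_mean:
            raise ConfigError(
                f"diurnal peak {self.diurnal_peak} below mean {self.diurnal_mean}"
            )
        if not 0 < self.mean_W <= 100:
            raise ConfigError(f"mean_W must be in (0, 100], got {self.mean_W}")
        if self.truth_model is not ModelSpec.RTW and self.truth_gamma is not None:
            pass  # gamma simply unused for single-driver truth models

    # -- derived quantities ------------------------------------------------

    def season_window(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        start = pd.Timestamp(f"{self.year}-{self.season[0]}")
        end = pd.Timestamp(f"{self.year}-{self.season[1]}") + pd.Timedelta(days=1)
        return start, end

    def campaign_dates(self) -> pd.DatetimeIndex:
        start = pd.Timestamp(f"{self.year}-{self.campaign_start}")
        end = pd.Timestamp(f"{self.year}-{self.season[1]}")
        return pd.date_range(start, end, freq=pd.Timedelta(days=self.campaign_every_days))

    def truth_alpha_centre(self) -> float:
        if self.truth_model is ModelSpec.RT:
            denom = math.exp(self.truth_beta * self.mean_T)
        elif self.truth_model is ModelSpec.RW:
            denom = self.mean_W ** self.truth_beta
        else:
            denom = (self.mean_T ** self.truth_beta) * (self.mean_W ** self.truth_gamma)
        return self.mean_R / denom

    def truth_fit(self, alpha: float) -> ModelFit:
        gamma = self.truth_gamma if self.truth_model is ModelSpec.RTW else None
        return ModelFit(model=self.truth_model, alpha=alpha, beta=self.truth_beta,
                        gamma=gamma)


# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------

def _even_grid(count: int, x0: float, y0: float, w: float, h: float) -> list[tuple[float, float]]:
    """Place `count` points on an even grid inside a rectangle."""
    cols = math.ceil(math.sqrt(count))
    rows = math.ceil(count / cols)
    pts = []
    for i in range(count):
        r, c = divmod(i, cols)
        pts.append(
            (x0 + (c + 0.5) * w / cols, y0 + (r + 0.5) * h / rows)
        )
    return pts


def _collar_layout(config: SyntheticConfig) -> list[tuple[str, float, float, int]]:
    w, h = config.plot_extent
    quadrants = {  # label -> (x0, y0), matching io_model.subplot_of
        1: (0.0, 0.0),
        2: (w / 2, 0.0),
        3: (w / 2, h / 2),
        4: (0.0, h / 2),
    }
    layout = []
    counter = 1
    for label, count in zip((1, 2, 3, 4), config.subplot_counts):
        x0, y0 = quadrants[label]
        for x, y in _even_grid(count, x0, y0, w / 2, h / 2):
            assert subplot_of(x, y, config.plot_extent) == label
            layout.append((f"C{counter:02d}", x, y, label))
            counter += 1
    return layout


# ---------------------------------------------------------------------------
# Drivers and campaign
# ---------------------------------------------------------------------------

def _driver_shapes(config: SyntheticConfig, grid: pd.DatetimeIndex) -> tuple[np.ndarray, np.ndarray]:
    """Shared T and W shape series (collar factors multiply these).

    The temperature shape is a seasonal sinusoid peaking mid-July plus a
    diurnal sinusoid peaking mid-afternoon, normalised to mean ``mean_T``
    over the season.  The moisture shape is an irrigation sawtooth
    (exponential decay restarting every irrigation), normalised to mean
    ``mean_W``.
    """
    day_of_year = grid.dayofyear.to_numpy() + grid.hour.to_numpy() / 24.0
    hour = grid.hour.to_numpy() + grid.minute.to_numpy() / 60.0
    peak_doy = pd.Timestamp(f"{config.year}-07-15").dayofyear
    T = (
        config.mean_T
        + config.seasonal_T_amplitude * np.cos(2 * np.pi * (day_of_year - peak_doy) / 365.0)
        + config.diurnal_T_amplitude * np.cos(2 * np.pi * (hour - 15.0) / 24.0)
    )
    season_start, season_end = config.season_window()
    in_season = (grid >= season_start) & (grid < season_end)
    T = T - T[in_season].mean() + config.mean_T

    t_days = (grid - grid[0]).total_seconds().to_numpy() / 86400.0
    phase = np.mod(t_days, config.irrigation_period_days)
    shape = np.exp(-phase / config.irrigation_decay_days)
    W = config.mean_W * shape / shape[in_season].mean()
    return T, W


def generate_campaign(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[CampaignTable, dict[str, ContinuousSeries]]:
    """Generate a campaign table and per-collar continuous logger series.

    Fully determined by ``config`` (and ``seed``, which overrides
    ``config.seed`` when given).  Per collar: lognormal factors scale the
    shared T/W driver shapes and the truth-model α; chamber observations at
    6-day dates pick a random 30-min slot inside the morning window and
    apply multiplicative lognormal noise to the modelled R.
    """
    config = config or SyntheticConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    rng = np.random.default_rng(config.seed)

    layout = _collar_layout(config)
    n = len(layout)
    tau = _lognormal_factors(rng, n, config.cv_T_spatial)     # T factors
    omega = _lognormal_factors(rng, n, config.cv_W_spatial)   # W factors
    alpha = config.truth_alpha_centre() * _lognormal_factors(rng, n, config.cv_alpha_spatial)

    # continuous grid: 1 June .. 30 September, 30-min cadence
    grid = pd.date_range(
        f"{config.year}-06-01", f"{config.year}-09-30 23:30", freq="30min"
    )
    T_shape, W_shape = _driver_shapes(config, grid)

    dates = config.campaign_dates()
    lo, hi = config.obs_window_hours
    slots = np.arange(math.ceil(lo * 2), math.floor(hi * 2)) / 2.0  # 30-min slots
    # one morning slot per date, shared by every collar: with zero spatial
    # CVs and zero noise all collars must be exactly identical
    date_hour = slots[rng.integers(0, slots.size, size=len(dates))]

    points: list[PointRecord] = []
    continuous: dict[str, ContinuousSeries] = {}
    for i, (collar_id, x, y, label) in enumerate(layout):
        T_i = tau[i] * T_shape + rng.normal(0.0, config.logger_noise_T, size=grid.size)
        W_i = omega[i] * W_shape * (
            1.0 + rng.normal(0.0, config.logger_noise_W_rel, size=grid.size)
        )
        W_i = np.clip(W_i, 0.05, 100.0)
        continuous[collar_id] = ContinuousSeries(
            collar_id=collar_id, timestamps=grid, T_series=T_i, W_series=W_i
        )
        truth = config.truth_fit(alpha[i])
        obs: list[Observation] = []
        for date, hour in zip(dates, date_hour):
            ts = date + pd.Timedelta(hours=hour)
            j = grid.get_loc(ts)
            T_obs, W_obs = float(T_i[j]), float(W_i[j])
            R_true = float(predict(truth, T=T_obs, W=W_obs))
            R_obs = R_true * float(rng.lognormal(
                -config.noise_sigma ** 2 / 2.0, config.noise_sigma
            )) if config.noise_sigma > 0 else R_true
            obs.append(Observation(ts.normalize(), R_obs, T_obs, W_obs))
        points.append(
            PointRecord(collar_id=collar_id, x_km=x, y_km=y, subplot=label,
                        observations=obs)
        )
    table = CampaignTable(points=points, plot_extent=config.plot_extent)
    table.validate()
    return table, continuous


def generate_diurnal(
    config: SyntheticConfig | None = None, seed: int | None = None,
    cadence: pd.Timedelta = pd.Timedelta(minutes=30),
) -> pd.Series:
    """Efflux series with a diurnal cycle over several days (preliminary run).

    R(t) = mean + (peak − mean)·cos(2π(h − p_d)/24) with the daily peak hour
    p_d jittered across days, so the daily mean equals ``diurnal_mean`` and
    the daily maximum ``diurnal_peak``.  Returns a pandas Series indexed by
    timestamps, suitable for :func:`fluxsample.seasonal_flux.representative_window`.
    """
    config = config or SyntheticConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    rng = np.random.default_rng(config.seed)

    start = pd.Timestamp(f"{config.year}-06-19")
    idx = pd.date_range(start, start + pd.Timedelta(days=config.diurnal_days),
                        freq=cadence, inclusive="left")
    day = (idx.normalize() - start).days.to_numpy()
    hour = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0 + idx.second.to_numpy() / 3600.0
    jitter = rng.uniform(-config.diurnal_peak_jitter_hours,
                         config.diurnal_peak_jitter_hours,
                         size=int(day.max()) + 1)
    peak_hour = config.diurnal_peak_hour + jitter[day]
    amplitude = config.diurnal_peak - config.diurnal_mean
    values = config.diurnal_mean + amplitude * np.cos(2 * np.pi * (hour - peak_hour) / 24.0)
    return pd.Series(values, index=idx, name="R")
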