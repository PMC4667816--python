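"""Seasonal integration unit conversions, gap rules, and the diurnal window."""

import numpy as np
import pandas as pd
import pytest

from fluxsample import (
    CoverageError,
    ModelFit,
    ModelSpec,
    RangeError,
    integrate_emission,
    representative_window,
)
from conftest import make_series

FLAT_RT = ModelFit(model=ModelSpec.RT, alpha=1.0, beta=0.0)  # predicts R = 1


def _flat_series(days, start="2012-06-01"):
    n = days * 48 + 1
    return make_series(np.full(n, 20.0), np.full(n, 25.0), start=start)


class TestIntegrateEmission:
    def test_one_day_unit_conversion(self):
        # 1 μmol m⁻² s⁻¹ over 86400 s = 0.0864 mol m⁻² = 1.03775 g C m⁻²
        series = _flat_series(2)
        est = integrate_emission(FLAT_RT, series, ("2012-06-01", "2012-06-02"))
        assert est.total_mol == pytest.approx(0.0864, rel=1e-12)
        assert est.total_gC == pytest.approx(1.0377504, rel=1e-12)
        assert est.total_gC == pytest.approx(est.total_mol * 12.011)
        assert est.total_gCO2 == pytest.approx(est.total_mol * 44.01)

    def test_zero_length_window(self):
        est = integrate_emission(FLAT_RT, _flat_series(2), ("2012-06-01", "2012-06-01"))
        assert est.total_mol == 0.0

    @pytest.mark.parametrize("alpha,days", [(0.5, 1), (2.0, 3)])
    def test_constant_model_closed_form(self, alpha, days):
        fit = ModelFit(model=ModelSpec.RT, alpha=alpha, beta=0.0)
        series = _flat_series(5)
        end = pd.Timestamp("2012-06-01") + pd.Timedelta(days=days)
        est = integrate_emission(fit, series, ("2012-06-01", end))
        assert est.total_mol == pytest.approx(alpha * days * 86400 * 1e-6, rel=1e-12)

    def test_additive_over_adjacent_windows(self):
        rng = np.random.default_rng(3)
        n = 6 * 48 + 1
        series = make_series(20 + rng.normal(0, 3, n), 25 + rng.normal(0, 2, n))
        fit = ModelFit(model=ModelSpec.RT, alpha=2.0, beta=0.08)
        whole = integrate_emission(fit, series, ("2012-06-01", "2012-06-05"))
        a = integrate_emission(fit, series, ("2012-06-01", "2012-06-03"))
        b = integrate_emission(fit, series, ("2012-06-03", "2012-06-05"))
        assert whole.total_mol == pytest.approx(a.total_mol + b.total_mol, rel=1e-10)

    def test_linear_in_alpha(self):
        series = _flat_series(3)
        base = ModelFit(model=ModelSpec.RT, alpha=1.0, beta=0.05)
        scaled = ModelFit(model=ModelSpec.RT, alpha=3.5, beta=0.05)
        w = ("2012-06-01", "2012-06-03")
        assert integrate_emission(scaled, series, w).total_mol == pytest.approx(
            3.5 * integrate_emission(base, series, w).total_mol, rel=1e-12
        )

    def test_trapezoid_step_convergence(self):
        # halving the step of a smooth series changes the integral < 0.1 %
        fit = ModelFit(model=ModelSpec.RT, alpha=2.0, beta=0.1)
        for freq, factor in (("30min", 48), ("15min", 96)):
            n = 4 * factor + 1
            t = np.arange(n) / factor
            T = 20 + 5 * np.sin(2 * np.pi * t)
            series = make_series(T, np.full(n, 25.0), freq=freq)
            est = integrate_emission(fit, series, ("2012-06-01", "2012-06-05"))
            if freq == "30min":
                coarse = est.total_mol
        assert est.total_mol == pytest.approx(coarse, rel=1e-3)

    def test_short_gap_interpolated_long_gap_rejected(self):
        series = _flat_series(10)
        frame_idx = series.timestamps
        # carve a 6 h hole: still integrable (drivers interpolated)
        keep = ~((frame_idx >= "2012-06-03 06:00") & (frame_idx < "2012-06-03 12:00"))
        short = make_series(series.T_series[keep], series.W_series[keep])
        short = short.__class__(
            collar_id="X", timestamps=frame_idx[keep],
            T_series=series.T_series[keep], W_series=series.W_series[keep],
        )
        est = integrate_emission(FLAT_RT, short, ("2012-06-01", "2012-06-08"))
        assert est.total_mol == pytest.approx(7 * 86400e-6, rel=1e-9)
        # a > 24 h hole is a coverage error
        keep = ~((frame_idx >= "2012-06-03") & (frame_idx < "2012-06-04 12:00"))
        long = short.__class__(
            collar_id="X", timestamps=frame_idx[keep],
            T_series=series.T_series[keep], W_series=series.W_series[keep],
        )
        with pytest.raises(CoverageError):
            integrate_emission(FLAT_RT, long, ("2012-06-01", "2012-06-08"))

    def test_window_outside_span_rejected(self):
        with pytest.raises(RangeError):
            integrate_emission(FLAT_RT, _flat_series(2), ("2012-05-01", "2012-06-02"))


def _diurnal(fn, days=3, step_minutes=1):
    per_day = 24 * 60 // step_minutes
    idx = pd.date_range("2012-06-19", periods=days * per_day,
                        freq=pd.Timedelta(minutes=step_minutes))
    h = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0
    return pd.Series(fn(h), index=idx)


class TestRepresentativeWindow:
    def test_constant_series_full_day(self):
        win = representative_window(_diurnal(lambda h: np.full_like(h, 4.5)))
        assert win.intervals == [(0.0, 24.0)]

    def test_small_amplitude_full_day(self):
        # amplitude 0.4 around 4.5 stays inside the 10 % band (0.45)
        win = representative_window(
            _diurnal(lambda h: 4.5 + 0.4 * np.sin(2 * np.pi * h / 24))
        )
        assert win.intervals == [(0.0, 24.0)]

    def test_sinusoid_band_width(self):
        # R = 4.5 + 2.5 sin(2πt/24): in-band where |sin| <= 0.18, two
        # intervals of width (24/π)·arcsin(0.18) ≈ 1.38 h at the crossings
        win = representative_window(
            _diurnal(lambda h: 4.5 + 2.5 * np.sin(2 * np.pi * h / 24))
        )
        expect = 24 / np.pi * np.arcsin(0.18)
        widths = sorted(e - s for s, e in win.intervals)
        assert len(win.intervals) == 2
        assert widths == pytest.approx([expect, expect], abs=0.1)
        centres = sorted(((s + e) / 2) % 24 for s, e in win.intervals)
        assert centres == pytest.approx([0.0, 12.0], abs=0.1) or centres == pytest.approx(
            [12.0, 24.0], abs=0.1
        )

    def test_band_wraps_midnight(self):
        # peak at 6:00 puts a mean crossing exactly at midnight, so one
        # in-band run must wrap around the end of the day
        win = representative_window(
            _diurnal(lambda h: 4.5 + 2.5 * np.cos(2 * np.pi * (h - 6) / 24))
        )
        assert any(e > 24.0 for s, e in win.intervals)  # wrapped interval

    def test_daily_mean_reported(self):
        win = representative_window(
            _diurnal(lambda h: 4.5 + 2.5 * np.sin(2 * np.pi * h / 24))
        )
        assert win.daily_mean == pytest.approx(4.5, rel=1e-6)

    def test_less_than_one_day_rejected(self):
        idx = pd.date_range("2012-06-19", periods=10, freq="30min")
        with pytest.raises(CoverageError):
            representative_window(pd.Series(np.ones(10), index=idx))
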