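"""Monte Carlo engine against its two independent oracles, plus invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluxsample import (
    CVCurve,
    SizeError,
    UndefinedCVError,
    ValidationError,
    closed_form_cv,
    exact_cv_enumeration,
    mc_cv_curve,
)
from fluxsample.mc_subsampling import closed_form_cv_curve, write_cv_curves

populations = st.lists(
    st.floats(min_value=0.1, max_value=1e3, allow_nan=False),
    min_size=4,
    max_size=10,
).filter(lambda v: np.std(v) > 1e-9 * max(abs(np.mean(v)), 1.0))


class TestOracles:
    def test_worked_enumeration_1234(self):
        # all 6 two-subsets of [1,2,3,4] have means {1.5,2,2.5,2.5,3,3.5};
        # mean squared deviation from 2.5 is 2.5/6 -> CV = 25.8199 %
        expect = math.sqrt(2.5 / 6) / 2.5 * 100
        assert expect == pytest.approx(25.8199, abs=1e-4)
        assert exact_cv_enumeration([1, 2, 3, 4], 2) == pytest.approx(expect, rel=1e-12)

    def test_enumeration_trivial_cases(self):
        assert exact_cv_enumeration([1, 2, 3, 4], 4) == 0.0
        assert exact_cv_enumeration([5, 5, 5], 2) == 0.0

    def test_closed_form_matches_hand_value(self):
        # S² = 5/3, Var = (5/6)·(1/2) -> same 25.8199 %
        assert closed_form_cv([1, 2, 3, 4], 2) == pytest.approx(25.8199, abs=1e-4)
        assert closed_form_cv([1, 2, 3, 4], 4) == 0.0

    def test_closed_form_k1_is_population_cv(self):
        vals = np.array([3.0, 5.0, 9.0, 11.0, 12.0])
        pop_cv = vals.std(ddof=0) / vals.mean() * 100
        assert closed_form_cv(vals, 1) == pytest.approx(pop_cv, rel=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(populations)
    def test_closed_form_equals_enumeration(self, values):
        # both oracles are exact for SRS without replacement; they must agree
        # to numerical precision for every k
        for k in range(1, len(values) + 1):
            a = exact_cv_enumeration(values, k)
            b = closed_form_cv(values, k)
            assert b == pytest.approx(a, rel=1e-10, abs=1e-12)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(populations)
    def test_closed_form_strictly_decreasing(self, values):
        cvs = [closed_form_cv(values, k) for k in range(1, len(values) + 1)]
        assert all(a > b for a, b in zip(cvs, cvs[1:]))

    def test_enumeration_guard(self):
        with pytest.raises(SizeError):
            exact_cv_enumeration(list(range(1, 41)), 20)


class TestMCCurve:
    def test_constant_population_zero_cv(self):
        curve = mc_cv_curve([3.0] * 6, M=200, seed=0)
        assert all(cv == 0.0 for cv in curve.cv_by_k.values())

    def test_matches_enumeration_small_population(self):
        curve = mc_cv_curve([1, 2, 3, 4], M=10_000, seed=11)
        assert curve.cv_by_k[2] == pytest.approx(25.8199, rel=0.03)

    def test_matches_closed_form_n51(self):
        # synthetic N=51 sample, mean 100, sample sd 10: closed form gives
        # CV_3 = sqrt((100/3)(1-3/51))/100 ≈ 5.60 %
        rng = np.random.default_rng(8)
        vals = rng.normal(100, 10, 51)
        vals = (vals - vals.mean()) / vals.std(ddof=1) * 10 + 100
        assert closed_form_cv(vals, 3) == pytest.approx(5.6011, abs=1e-3)
        curve = mc_cv_curve(vals, M=10_000, seed=1)
        assert curve.cv_by_k[3] == pytest.approx(closed_form_cv(vals, 3), rel=0.03)

    def test_determinism_bit_identical(self):
        vals = np.random.default_rng(0).uniform(1, 9, 12)
        a = mc_cv_curve(vals, M=500, seed=42)
        b = mc_cv_curve(vals, M=500, seed=42)
        assert a == b
        assert a.cv_by_k == b.cv_by_k

    def test_different_seed_differs(self):
        vals = np.random.default_rng(0).uniform(1, 9, 12)
        a = mc_cv_curve(vals, M=500, seed=1)
        b = mc_cv_curve(vals, M=500, seed=2)
        assert a.cv_by_k != b.cv_by_k

    @pytest.mark.parametrize("scale", [3.0, 0.25, -1.0])
    def test_scale_invariance(self, scale):
        vals = np.array([2.0, 4.0, 5.0, 9.0, 10.0])
        base = mc_cv_curve(vals, M=2000, seed=5)
        scaled = mc_cv_curve(scale * vals, M=2000, seed=5)
        for k in base.ks:
            assert scaled.cv_by_k[k] == pytest.approx(base.cv_by_k[k], rel=1e-12)
            assert scaled.cv_by_k[k] >= 0.0

    def test_curve_shape_and_metadata(self):
        vals = [1.0, 2.0, 4.0, 8.0]
        curve = mc_cv_curve(vals, M=100, seed=9, variable="T")
        assert curve.N == 4 and curve.M == 100 and curve.seed == 9
        assert curve.ks == [1, 2, 3]
        assert curve.E_N == pytest.approx(np.mean(vals))

    @pytest.mark.parametrize(
        "values,M,err",
        [
            ([1.0], 100, SizeError),             # N < 2
            ([1.0, -1.0], 100, UndefinedCVError),  # mean zero
            ([1.0, 2.0, 3.0], 1, ValidationError),  # M < 2
        ],
    )
    def test_preconditions(self, values, M, err):
        with pytest.raises(err):
            mc_cv_curve(values, M=M, seed=0)

    def test_cvcurve_entry_count_enforced(self):
        with pytest.raises(ValidationError):
            CVCurve(variable="x", N=4, M=10, E_N=1.0, cv_by_k={1: 0.1}, seed=0)


def test_mc_within_tolerance_of_enumeration_sweep():
    # a handful of fixed small populations, every k: 3 % relative agreement
    rng = np.random.default_rng(77)
    for n in range(4, 9):
        values = rng.uniform(1, 50, n)
        curve = mc_cv_curve(values, M=10_000, seed=int(rng.integers(2**31)))
        for k in range(1, n):
            exact = exact_cv_enumeration(values, k)
            assert curve.cv_by_k[k] == pytest.approx(exact, rel=0.03)


def test_csv_roundtrip(tmp_path):
    import pandas as pd

    vals = np.random.default_rng(1).uniform(1, 9, 8)
    curves = [mc_cv_curve(vals, M=300, seed=s, variable=v)
              for s, v in ((1, "T"), (2, "W"))]
    path = tmp_path / "curves.csv"
    write_cv_curves(curves, path)
    df = pd.read_csv(path)
    assert list(df.columns) == ["variable", "N", "M", "seed", "k", "cv_percent"]
    assert len(df) == 2 * 7
    back = df[df.variable == "T"].set_index("k")["cv_percent"].to_dict()
    assert back == pytest.approx(curves[0].cv_by_k)


def test_closed_form_curve_helper():
    vals = np.array([2.0, 3.0, 5.0, 8.0, 13.0])
    curve = closed_form_cv_curve(vals, variable="W")
    assert curve.ks == [1, 2, 3, 4]
    for k in curve.ks:
        assert curve.cv_by_k[k] == pytest.approx(closed_form_cv(vals, k), rel=1e-12)
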