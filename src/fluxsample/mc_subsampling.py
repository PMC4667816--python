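"""Monte Carlo subsampling engine: CV of the subsample mean at every size k.

Given one value per collar (mean T, mean W, or seasonal emission), the
engine quantifies how the precision of a plot-scale estimate depends on how
many collars are sampled.  For each subsample size k = 1..N−1 it draws
M random subsamples *without replacement* (a fresh uniformly random
permutation of the collar indices, truncated to its first k entries — simple
random sampling without replacement), takes each subsample mean E_i, and
reports the coefficient of variation of those means around the full-sample
mean E_N:

    CV_k = sqrt( (1/(M−1)) · Σ_i (E_i − E_N)² ) / |E_N| × 100   [%]

Deviations are centred on E_N (not on the mean of the E_i) and the divisor
is M−1; both choices are kept deliberately even though they differ from the
textbook sd estimator by O(1/M).  Duplicate subsamples across the M draws
are permitted — at M = 10,000 their effect is negligible.

Two independent oracles validate the engine: exhaustive enumeration of all
C(N, k) subsets (the M→∞ limit, divisor = number of subsets) and the
survey-sampling closed form based on the finite-population correction,
Var(Ē_k) = (S²/k)·(1 − k/N) with S² the (N−1)-divisor sample variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import NumericalError, ValidationError

__all__ = [
    "DEFAULT_M",
    "SizeError",
    "UndefinedCVError",
    "CVCurve",
    "mc_cv_curve",
    "exact_cv_enumeration",
    "closed_form_cv",
    "write_cv_curves",
]

#: default number of random subsample draws per size k
DEFAULT_M = 10_000

#: guard for the exhaustive oracle
MAX_ENUMERATION = 1_000_000


class SizeError(ValidationError):
    """Sample too small (or enumeration too large) for the operation."""


class UndefinedCVError(ValidationError):
    """Full-sample mean is zero: the CV is undefined."""


@dataclass(frozen=True)
class CVCurve:
    """CV of the subsample mean at every size k = 1..N−1, with provenance.

    ``cv_by_k`` maps k to CV_k in percent.  ``seed`` and ``M`` record how the
    curve was produced so it can be regenerated bit-identically.
    """

    variable: str
    N: int
    M: int
    E_N: float
    cv_by_k: dict[int, float] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        if len(self.cv_by_k) != self.N - 1:
            raise ValidationError(
                f"cv_by_k must have N-1 = {self.N - 1} entries, got {len(self.cv_by_k)}"
            )

    @property
    def ks(self) -> list[int]:
        return sorted(self.cv_by_k)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.variable,
                "N": self.N,
                "M": self.M,
                "seed": self.seed,
                "k": self.ks,
                "cv_percent": [self.cv_by_k[k] for k in self.ks],
            }
        )


def _check_population(values) -> tuple[np.ndarray, float]:
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1:
        raise ValidationError("values must be one-dimensional (one per collar)")
    if not np.all(np.isfinite(vals)):
        raise ValidationError("values must be finite")
    if vals.size < 2:
        raise SizeError(f"need N >= 2 collars, got {vals.size}")
    mean = float(vals.mean())
    if mean == 0.0:
        raise UndefinedCVError("full-sample mean is zero; CV undefined")
    return vals, mean


def mc_cv_curve(
    values: Sequence[float],
    M: int = DEFAULT_M,
    seed: int | None = None,
    variable: str = "custom",
) -> CVCurve:
    """Monte Carlo CV-versus-sample-size curve for one per-collar variable.

    For each k, M subsamples are drawn by truncating independent random
    permutations of 1..N to their first k entries; one fresh permutation is
    used per draw and per k.  The random stream is a seeded
    ``numpy.random.default_rng`` consumed in ascending k, so identical
    inputs and seed give a bit-identical curve.
    """
    vals, E_N = _check_population(values)
    N = vals.size
    if M < 2:
        raise ValidationError(f"need M >= 2 draws, got {M}")
    rng = np.random.default_rng(seed)
    base = np.tile(np.arange(N), (M, 1))
    cv_by_k: dict[int, float] = {}
    for k in range(1, N):
        idx = rng.permuted(base, axis=1)[:, :k]
        E_i = vals[idx].mean(axis=1)
        cv = math.sqrt(float(np.sum((E_i - E_N) ** 2)) / (M - 1)) / abs(E_N) * 100.0
        cv_by_k[k] = cv
    return CVCurve(variable=variable, N=N, M=M, E_N=E_N, cv_by_k=cv_by_k, seed=seed)


def exact_cv_enumeration(values: Sequence[float], k: int) -> float:
    """Brute-force oracle: CV over *every* k-subset of the population.

    Enumerates all C(N, k) subsets once, so the divisor is the subset count —
    the M→∞ limit of the Monte Carlo estimator.  Guarded at C(N, k) ≤ 1e6.
    """
    vals, E_N = _check_population(values)
    N = vals.size
    if not 1 <= k <= N:
        raise SizeError(f"k must be in 1..{N}, got {k}")
    n_subsets = math.comb(N, k)
    if n_subsets > MAX_ENUMERATION:
        raise SizeError(
            f"C({N}, {k}) = {n_subsets} exceeds enumeration guard {MAX_ENUMERATION}"
        )
    sq = 0.0
    for subset in combinations(vals, k):
        sq += (math.fsum(subset) / k - E_N) ** 2
    return math.sqrt(sq / n_subsets) / abs(E_N) * 100.0


def closed_form_cv(values: Sequence[float], k: int) -> float:
    """Survey-sampling oracle: CV of the mean under SRS without replacement.

    Uses Var(Ē_k) = (S²/k)·(1 − k/N) with S² the (N−1)-divisor variance —
    the finite-population correction shrinks the variance to 0 at k = N.
    At k = 1 this equals the population CV (N-divisor sd over the mean).
    """
    vals, E_N = _check_population(values)
    N = vals.size
    if not 1 <= k <= N:
        raise SizeError(f"k must be in 1..{N}, got {k}")
    S2 = float(vals.var(ddof=1))
    var_mean = (S2 / k) * (1.0 - k / N)
    return math.sqrt(var_mean) / abs(E_N) * 100.0


def closed_form_cv_curve(values: Sequence[float], variable: str = "custom") -> CVCurve:
    """Full analytic CV curve (k = 1..N−1) from the closed form."""
    vals, E_N = _check_population(values)
    N = vals.size
    return CVCurve(
        variable=variable,
        N=N,
        M=0,
        E_N=E_N,
        cv_by_k={k: closed_form_cv(vals, k) for k in range(1, N)},
        seed=None,
    )


def write_cv_curves(curves: Sequence[CVCurve] | CVCurve, path) -> None:
    """Write one or more CV curves to CSV: variable, N, M, seed, k, cv_percent."""
    if isinstance(curves, CVCurve):
        curves = [curves]
    pd.concat([c.to_frame() for c in curves], ignore_index=True).to_csv(path, index=False)
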