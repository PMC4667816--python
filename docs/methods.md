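# Methods

This note records the scientific and numerical choices behind
`fluxsample`, in the package's own terms: what is modelled, what the
synthetic world does and does not emulate, and where the design was
genuinely open.

## Estimand and sampling model

The unit of observation is a chamber collar; the estimand is the plot mean
of a per-collar quantity (campaign-mean soil temperature T, campaign-mean
volumetric water content W, or modelled growing-season CO₂ emission). The
collar set of size N is treated as a *finite population*: uncertainty from
sampling n < N collars is quantified by simple random sampling without
replacement (SRSWOR), realised as a uniformly random permutation of the
collar indices truncated to its first k entries, one fresh permutation per
draw and per k.

The reported statistic is

    CV_k = sqrt( (1/(M−1)) · Σ_{i=1..M} (E_i − E_N)² ) / |E_N| × 100  [%]

with E_i the i-th subsample mean and E_N the full-sample mean. Two
deliberate non-textbook details are kept because they define the method
being implemented: deviations are centred on E_N rather than on the mean
of the E_i, and the divisor is M−1 even though the M→∞ limit uses M. Both
differ from the usual sd estimator by O(1/M), invisible at the default
M = 10,000. The absolute value in the denominator makes CV_k ≥ 0 and
sign-flip invariant; for the positive-valued field variables it is a no-op.

Two independent oracles bound the engine: exhaustive enumeration over all
C(N,k) subsets (exact M→∞ limit, guarded at 10⁶ subsets), and the
survey-sampling closed form Var(Ē_k) = (S²/k)(1 − k/N) with S² the
(N−1)-divisor variance. The two oracles are algebraically identical; the
test suite verifies them against each other to 1e-10 and the MC engine
against both to 3 % relative (MC noise at M = 10,000 has a relative sd of
roughly 1/√(2M) ≈ 0.7 %, so 3 % is a ≈4σ band).

## Response models and fitting

Three empirical models per collar: R = α·e^(βT), R = α·W^β,
R = α·T^β·W^γ. Fitting minimises Σ(R_obs − R_pred)² on the original scale
(not the log scale) with `scipy.optimize.least_squares`
(Levenberg–Marquardt, ftol/xtol/gtol = 1e-10, iteration cap 500).
Starting values come from the closed-form ordinary least squares fit on
the log scale, which removes any dependence on arbitrary initial guesses
for these smooth 2–3 parameter problems; if the refined optimum is ever
worse than the start (pathological data), the start is returned, so the
reported SS_res never exceeds the log-linear baseline. R² = 1 − SS_res/SS_tot
on the untransformed scale, allowed to be negative; constant R (SS_tot = 0)
is an error, not R² = 1. Per-model campaign summaries report the mean R²
across collars ± sd/√(collars).

Preconditions follow the models' domains: R > 0 always (log start),
W > 0 for the moisture models, T > 0 (°C) only for the interactive model,
where T is raised to a real power; the exponential model accepts any T.
Fits use campaign-day observations only — the only dates with co-located
R — never the continuous logger data.

## Seasonal integration

Per collar, the fitted model is evaluated on the 30-min logger grid and
integrated by the trapezoidal rule over the growing season, by default
16 June 00:00 – 19 September 24:00 (configurable; the chamber campaign
itself starts earlier, on 6 June). Logger gaps shorter than 24 h are
bridged by linear interpolation of the *drivers* T and W on the 30-min
grid — drivers vary smoothly while the flux is a nonlinear map of them, so
interpolating R itself would bias the integral; longer gaps are a coverage
error. Unit chain: μmol m⁻² s⁻¹ × s × 1e-6 → mol CO₂ m⁻², × 12.011 →
g C m⁻², × 44.01 → g CO₂ m⁻² (both masses are reported since "emission"
is conventionally quoted in either).

The representative diurnal window averages an efflux series across days at
each time of day and returns the maximal time-of-day intervals (wrapping
midnight; a wrapped interval is reported with end > 24 h) where the mean
cycle stays within ±10 % (configurable) of its daily mean — the rationale
for a mid-morning once-daily measurement slot.

## Optimal sample size

The slope of the CV curve is the forward difference s_n = CV_{n+1} − CV_n
assigned to n (% per collar). n\* is the smallest n with s_n strictly
above the threshold −1.0; a tie does not exceed it. The discretisation was
an open choice — the forward difference is used because it reproduces the
described behaviour exactly: slopes below the threshold strictly before
n\*, above it from n\* on. If every slope is below the threshold the
result is "not obtained" rather than N−1: the plot's collar count is too
small for the curve to flatten. Plot densities in the design table are
recomputed from the stated geometry (count / area) rather than taken from
any external tabulation.

## Error propagation

Total derivatives of the three models give ΔR/R = β·ΔT, β·ΔW/W, and
β·ΔT/T + γ·ΔW/W respectively. The exponential form genuinely takes an
*absolute* ΔT (its sensitivity is β per °C) while the power laws take
relative errors — the inputs are therefore split into `delta_T` (°C) and
`delta_W_rel` (dimensionless) rather than forced into one convention. The
interactive form sums its two terms, implicitly treating T and W errors as
independent; no covariance term is added. When driven from a CV curve the
mapping is ΔW/W = CV_k/100 and ΔT = (CV_k/100)·T̄ — a stated convention of
this package, since CVs are relative by construction.
`linearization_check` validates the first-order formulas against the exact
model ratio; the discrepancy decays quadratically in the perturbation
(delta-method remainder), which the acceptance suite verifies over
perturbations 10⁻¹..10⁻³.

## Synthetic world

The generator emulates an irrigated-maize campaign: 51 collars on an even
grid over a 5×5 km² plot, quadrant subplots (SW/SE/NE/NW) holding
15/15/12/9 collars — the unique split under which the four contiguous
half-plot pairings contain 30/27/24/21 points — chamber visits every
6 days from 6 June to 19 September in a shared random 30-min slot between
8:30 and 12:00, and continuous 30-min loggers from 1 June to 30 September.

Across-collar heterogeneity is multiplicative lognormal (mean-1 factors,
CV-parameterised), guaranteeing positive T scales, W and α: collar factors
multiply a shared temperature shape (seasonal sinusoid peaking 15 July,
amplitude 4 °C, plus a diurnal sinusoid peaking 15:00, amplitude 5 °C,
normalised to a 20 °C season mean) and a shared irrigation sawtooth for W
(exponential decay, 5-day time constant, restarting every 11 days,
normalised to a 25 % season mean). The 11-day irrigation cycle is
deliberately incommensurate with the 6-day visit cadence: a 12-day cycle
would alias, with every collar sampled at only two wet–dry phases.
Defaults: spatial CV 5 % (T), 10 % (W); truth model R = α·T^1.649·W^0.622
(coefficient centres chosen site-plausible from the stable large-n regime
of such campaigns) with α set to give R = 4.5 μmol m⁻² s⁻¹ at (20 °C,
25 %) and spatial CV 4 %, which propagates to a seasonal-emission spatial
CV of ≈ √((1.649·0.05)² + (0.622·0.10)² + 0.04²) ≈ 11 %; chamber noise is
multiplicative lognormal with log-sd 0.1. The diurnal-cycle generator
(preliminary-experiment emulation) produces mean 4.5 / peak
7.0 μmol m⁻² s⁻¹ with the peak hour jittered ±1 h across days.

What the generator does *not* emulate — and hence what a green test does
not establish: spatial autocorrelation (collars are drawn independently;
the subsampling procedure itself is permutation-based and ignores
position, so this is consistent but means "subplot" results differ from
the full plot only through which collars they contain), real irrigation
scheduling (shared phase across the plot), instrument drift, and any
hysteresis or photosynthesis-driven respiration dynamics. Reported
field-campaign numbers from real plots are data-specific and are not
reproduction targets; the tests assert structural properties (oracle
agreement, recovery, orderings) instead.

## Degenerate inputs and tie-breaks

- Zero-variance populations give CV_k = 0 at every k and n\* = 1.
- E_N = 0 is an undefined-CV error (no silent infinities).
- A collar with observations but no valid (non-missing) values is an
  error; missing single values are skipped in means.
- Subplot labels are quadrants with half-open boundaries (a collar exactly
  on the centre line belongs to the east/north side).
- `design_table` derives one child seed per (partition, variable) from the
  master seed via `numpy.random.SeedSequence`, so adding a partition does
  not shift the random stream of the others; all seeds stay below 2³¹.

## Known limitations

- Exhaustive enumeration is guarded at 10⁶ subsets; for N = 51 only very
  small or very large k are enumerable — by design, it is an oracle, not a
  production path.
- The NLS fit assumes additive error on the original scale while the
  generator's noise is multiplicative; this mild misspecification is
  intentional (it mirrors field practice) and is why noisy-recovery tests
  use median-error bounds.
- `representative_window` assumes a uniform cadence that divides 24 h.
- The CV-to-Δ mapping in the propagation stage is a convention; if driver
  errors are estimated another way, pass ΔT and ΔW/W directly.
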