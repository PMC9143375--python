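# Methods

## Model

The Maxwell form of the standard linear solid (SLS): a spring `E1` (Pa) in
parallel with a Maxwell arm of spring `E2` (Pa) and dashpot `η` (Pa·s).  The
governing relation is

    σ + τR σ̇ = E1 (ε + τC ε̇),   τR = η/E2,   τC = η (E1+E2) / (E1 E2),

with `τC > τR` strictly for all positive parameters.  `E1` is the
equilibrium modulus, `E1 + E2` the instantaneous modulus.  The model is
linear, isotropic and history-independent beyond the single internal
relaxation mode; all computation is one-dimensional and in SI units.

For a **strain-controlled ramp-hold** test (rate `r` 1/s, hold strain `ε0`)
the stress is

    ramp:  σ(t) = E1 r t + E1 r (τC − τR)(1 − e^(−t/τR)),      0 ≤ t ≤ ε0/r
    hold:  σ(t) = A_R e^(−(t/τR)^k) + E1 ε0,                    t = 0 at hold start
           A_R = E1 r (τC − τR)(1 − e^(−ε0/(τR r)))  > 0

and for a **stress-controlled ramp-hold** test (rate `r` Pa/s, hold stress
`σ0`) the strain is

    ramp:  ε(t) = (r/E1) t + (r/E1)(τR − τC)(1 − e^(−t/τC)),   0 ≤ t ≤ σ0/r
    hold:  ε(t) = A_C e^(−(t/τC)^k) + σ0/E1,
           A_C = (r/E1)(τR − τC)(1 − e^(−σ0/(τC r)))  < 0.

The hold amplitudes carry the entire ramp history.  Their limits anchor the
two classical regimes: as `r → ∞`, `A_R → E2 ε0` and
`A_C → −σ0 E2 / (E1(E1+E2))`, recovering the step-loading (infinite-rate)
solutions; as `r → 0` both amplitudes vanish — the specimen equilibrates
during loading and the hold curve carries no viscoelastic information.

The stretch exponent `k ∈ (0, 1]` (Kohlrausch) broadens the hold-phase
decay to fit real materials; it applies to the hold phase only, which is
exactly where a single-mode model under-fits measured curves.  `k = 1` is
the pure SLS solution and is what the simulator generates.

Numerical note: every `1 − e^(−x)` factor is evaluated with `expm1`, so
fast ramps (`x = ε0/(τR r) → 0`) do not suffer catastrophic cancellation.

## Simulator

`simulate_relaxation` / `simulate_creep` evaluate the closed forms at a
uniform per-phase sampling (defaults: 200 ramp points, 1000 hold points; a
ramp plan below 10 points is densified to 50 and a warning recorded on the
curve).  The rationale for a *material-point* simulator: for a linear,
isotropic, homogeneous specimen under uniform uniaxial ramp-hold loading,
every material point obeys the same 1-D SLS relation, so the specimen-level
curve equals the point-level curve.  What this surrogate deliberately does
**not** model: near-incompressibility effects, boundary-condition
non-uniformity, mesh discretisation error — features of a finite-element
study of a 3-D specimen.  Consequently, passing benchmarks here validate
the constitutive equations and estimators, not FE-specific artifacts (e.g.
any dependence of creep errors on the absolute modulus, which in an exact
linear surrogate cancels out of relative errors).

`method="ode"` integrates the governing relation itself (LSODA, rtol 1e-9,
atol 1e-12 × the channel scale) piecewise over ramp and hold, evaluated at
the same sample times — an independent oracle for the closed forms, checked
to 1e-6 relative agreement across the benchmark grid (1e-5 at the two
fastest rates, whose ramps span only a small fraction of a relaxation
time).

Noise, when requested, is multiplicative Gaussian on the measured channel
(stress for relaxation, strain for creep), seeded through
`numpy.random.default_rng`.

## Benchmark grid

Nine hydrogel-like materials spanning the soft-tissue range: elastic
modulus `E = E1 ∈ {5, 10, 30}` kPa crossed with `τR ∈ {0.5, 2, 5}` s at
relaxation fraction `g = E2/(E1+E2) = 0.8` (so `E2 = 4 E1`, `η = τR E2`).
Relaxation trials hold `ε0 = 0.01` and sweep strain rates
`10^-4 … 10^2` 1/s in decades; creep trials hold `σ0 = 100` Pa and sweep
stress rates `1 … 10^6` Pa/s — ramp durations 100 s down to 0.1 ms in both
cases.  Hold durations are 8 governing time constants (8 τR for relaxation,
8 τC for creep), chosen so the plateau is reached to well under 1% — the
equilibrium level is what pins `E1` in every estimator.

## Estimators

All fits act on the **hold phase only** (the conventional relaxation/creep
curve), with the loading rate and hold level fixed — taken from the declared
protocol or recovered from the data (`estimate_protocol`: least-squares
ramp slope, hold-phase mean).

* Finite-rate fits: free `(E1, τR, τC, k)`.  The time-constant pair is
  parameterised as base constant × `(1 + δ)`, `δ > 0` (base `τR` for
  relaxation, `τC` for creep), so `τC > τR` holds by construction inside
  the optimizer.  `E2` and `η` follow algebraically.  `k` may be pinned at
  1 (`fit_k=False`); the default fits it, bounded to `(10^-3, 1]`.
* Infinite-rate fits: free `(E1, E2, τR)` (relaxation) or `(E1, E2, τC)`
  (creep); `η = τR E2` or `η = τC E1 E2/(E1+E2)`.

Optimisation is bounded trust-region least squares (`scipy.optimize.
least_squares`, trf, ftol = xtol = gtol = 1e-12), initialised from the data:
equilibrium level from the last-decile mean (→ `E1`), decay amplitude from
the first hold sample minus equilibrium, time constant from the 1/e
crossing of the normalised decay (linear interpolation), `k = 1`, and the
second time constant from inverting the amplitude expression.  On
non-convergence the solve restarts up to three times from deterministically
scaled initial points (×0.6, ×1.6, ×0.3) and keeps the lowest-cost result;
the `converged` flag reports the optimizer status.

Identifiability: when the fitted decay amplitude falls below 1e-3 of the
hold-signal scale the transient is numerically invisible and `E2`/`η`
(which live only in the amplitude and decay) are ill-determined;
`condition_warning` flags the result.  This is the practical failure mode
of slow-ramp creep tests: `A_C → 0` as `r → 0`.

The accuracy metric is the absolute relative error
`|estimated − true| / true` per parameter, with 5% as the accuracy
criterion.  Errors are reported as positive magnitudes.

## Study pipeline

`run_sweep` simulates the full grid for one test kind and fits every curve
with each requested form, emitting a tidy table (one row per material ×
rate × form × parameter); failed fits become flagged rows, never gaps, and
the noiseless pipeline is bitwise deterministic.  `detect_threshold`
reports the smallest grid rate at which the error is below criterion there
and at every faster grid rate — a grid member, not an interpolated
crossing, since sub-decade resolution would overstate the precision of the
7-point rate sweep.  `threshold_vs_tauR` pivots thresholds by modulus and
`τR`, expressing the observation that faster-relaxing materials need faster
loading for the step forms (and, in creep, for `E2` generally) to be
accurate.

## Design choices

* Time origin restarts at each hold phase; curves store a global clock plus
  a `phase` column, and estimators re-zero internally.  The CSV schema is
  `time_s, stress_Pa, strain, phase` with a JSON sidecar for protocol,
  generating parameters, noise spec and warnings.
* The stretch exponent is a plain validated float rather than a wrapper
  type; parameter containers are frozen dataclasses with constructor
  validation.
* Noise-robustness checks use the softest and stiffest benchmark materials
  at the central grid rates (0.1 1/s; 1000 Pa/s), 1% relative noise, median
  over 20 seeds — a spot check of estimator stability, not a full
  uncertainty analysis.
* Degenerate inputs: non-positive or non-finite parameters, `g ∉ (0,1)`,
  `k ∉ (0,1]`, negative times, ramp-window violations and `τC ≤ τR` all
  raise `ValueError` naming the offending quantity.

## Limitations

Single relaxation mode only (no generalized Maxwell/Kelvin or fractional
models); linear theory (no large-strain or nonlinear viscoelasticity); the
material-point surrogate cannot exhibit specimen-level FE effects; the
stretched exponent improves fit flexibility but its estimate trades off
against the time constant on noisy data; thresholds are resolved only to
the decade grid.
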