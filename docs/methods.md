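# Methods

## The transport model and its assumptions

A dwelling is modelled as n well-mixed indoor zones exchanging air with
each other and with outdoors (zone 0). The airflow field is a matrix
`Q[i][j]` (m³/h, from i to j, diagonal zero). Three assumptions make the
tracer balances algebraic:

1. **Steady state.** Dosers run long enough (>12 h in practice) before
   sampling that concentrations are stationary over the 24-h sampling
   window. The model does not attempt to verify this; it is an input
   assumption, and how long equilibration truly takes in rooms of a given
   volume is not modelled.
2. **Perfect mixing per zone.** One concentration represents a room. The
   survey design mitigates (not removes) the error this introduces by
   placing four dosers at the room corners and sampling at the centre, so
   the measured dilution reflects emission-like source placement — this is
   what makes the recovered quantity an *effective* air exchange rate.
3. **Zero outdoor tracer concentration.** Perfluorocarbons have negligible
   ambient background at the µg/m³ scale of indoor dosing. A nonzero
   background is a declared non-goal.

Under these, tracer T emitted at M_T µg/h in source zone src(T) satisfies,
for every indoor zone i:

    M_T·[i = src(T)] + Σ_{j≠i} C_Tj·Q_ji − C_Ti·(Q_i0 + Σ_{j≠i} Q_ij) = 0

The forward solver assembles the shared (n×n) transport operator once and
solves one dense linear system per tracer. A zone with zero total outflow
(or a connected component with no exhaust path) makes the operator
singular; this raises an explicit ill-posed-system error rather than
returning NaNs. Before solving, per-zone air closure

    residual_i = Q_0i + Σ_j Q_ji − Q_i0 − Σ_j Q_ij

is checked against a tolerance (default 1e-6 m³/h). Note the air-balance
rows are implemented in this physically closed form (inflow = outflow per
zone); published renderings of these equations sometimes carry sign/index
typos that would make the system degenerate.

A balanced field exhausts exactly what it is dosed: Σ_i C_Ti·Q_i0 = M_T.
This mass-closure identity is tested to 1e-9 relative and is the cheapest
diagnostic of a broken flow field.

## The inversion

With one tracer per zone and measured C, the n² tracer balances plus n air
balances are **linear** in the n² + n unknown flows (12 equations, 12
unknowns for 3 zones). The estimator stacks them as `G q = d` and solves

    min ‖G q − d‖²  subject to  q ≥ 0

- `method="nnls"` (default): `scipy.optimize.nnls`, the exact minimiser of
  this convex problem — deterministic and free of starting-point choices.
- `method="bounded_quasi_newton"`: L-BFGS-B on the same objective with
  bounds, the route traditionally used with spreadsheet solvers. It exists
  as a cross-check; on every instance its objective must match NNLS (the
  tests compare them at 1e-8 relative, treating objectives below the
  machine scale 1e-12·‖d‖² as both-zero, since the square system often has
  an interior exact solution and both objectives are then ~0).

Numerical choices for the quasi-Newton route: variables are column-scaled
(the raw columns mix µg/h and m³/h magnitudes and the unscaled quadratic
stalls L-BFGS-B's line search about two decades short); the starting point
is all flows equal to Σ M_T / Σ C_T,src (the single-zone heuristic);
objective tolerance 1e-12 and gradient tolerance 1e-14, both configurable.
Non-convergence is flagged in `solver_info`, never silently dropped.

**Constraint closure.** The bound is implemented as Q ≥ 0 rather than
strict positivity: least squares needs a closed feasible set, and a zero
flow is physically meaningful (a sealed pathway).

**Residual weighting.** Tracer rows carry µg/h, air rows m³/h, and the
traditional formulation sums raw squares across those mixed units. Default
mode `"raw"` reproduces that behaviour deliberately; mode `"normalized"`
divides each tracer row by its M_T and each air row by a total-exhaust
estimate (Σ_T M_T / C_T,src), making all rows dimensionless. In the exact
noiseless case both modes recover the same flows; under noise they weight
errors differently, and the package exposes rather than hides that choice.

**Identifiability.** If `G` is rank-deficient (e.g. two zones with
proportional concentration columns) the measurement cannot pin down all
flows; the estimator raises a non-identifiable error instead of returning
one of the infinitely many minimisers. Degenerate inputs (all-zero
concentrations, a tracer absent from its own source room) are rejected
with explicit errors.

**Rates and aggregation.** Outdoor ACH_i = Q_0i/V_i and inter-room
ACH_i = Σ_j Q_ji/V_i (h⁻¹). Daily aggregation reports element-wise mean
and sample SD (n−1); with a single day the SD is reported as absent, never
as zero. Monte-Carlo uncertainty propagation re-inverts measurements
perturbed by mean-preserving multiplicative lognormal noise at given CVs
and reports 2.5/50/97.5 percentiles; failed draws are counted and the run
aborts if more than a configurable fraction (default 20%) fail.

## Calibration chain

All internal units are fixed (flows m³/h, air concentrations µg/m³,
extract concentrations µg/mL, dosing rates µg/h internally, mg/h at the
I/O boundary); conversions happen only in the I/O layer.

- **Recovery efficiency**: mean and sample SD of measured/spiked over
  replicate spiked cartridges. The spike mass is an explicit input (the
  procedure is the same at 1 µg or 10 µg per cartridge; the operation does
  not assume either).
- **Sampling rate**: SR = adsorbed mass / (chamber concentration × time),
  in mL/min — the equivalent air volume drawn per minute by diffusion.
- **Analytical limits**: LOD = 3σ, LOQ = 10σ of the blank; their ratio is
  10/3 by construction whenever both derive from the same σ.
- **24-h air limits**: limit_air = analytical_limit × V_extract/(SR·t).
  The default extract volume is 1.0 mL — with that value and **no recovery
  correction** the published 24-h limits for the three tracers
  (0.20/0.17/0.26 µg/m³ detection, 0.66/0.58/0.85 µg/m³ quantification)
  are reproduced exactly from their analytical limits and sampling rates.
  A recovery-corrected mode (divide by recovery; conservative, higher
  limits) is available.
- **Concentration from a sampler extract**:
  C = mass/(recovery × SR × t). Unlike the limit formula this **does**
  divide by recovery — otherwise concentrations would be biased low by the
  unrecovered fraction (16–60% for these tracers). This asymmetry is
  deliberate and is the one place a user must be careful when comparing a
  concentration against a limit.
- **Gravimetric dosing rate**: OLS slope (with intercept) of cumulative
  weight loss vs time; slope SE and R² reported; a negative fitted rate is
  flagged. An apparent weight *gain* between weighings larger than
  3×1.4826×MAD of the release increments triggers a warning (a robust
  scale is used because the artefact itself would inflate an SD estimate).
  Robust slope fitting is out of scope.
- **Temperature model**: dosing rates grow exponentially with temperature;
  R(T) = a·e^(bT) is fit log-linearly, requiring strictly positive rates.

Reported limits are rounded to 2 decimals and rates to short precision
only at the reporting layer; all internal values keep full precision.

## CO₂ decay reference method

A charged room decays as C(t) = B + (C₀−B)·e^(−λt); λ is minus the OLS
slope of ln(C−B) vs t. The baseline B is a required explicit argument
(400 ppm is typical outdoors but is never applied silently). Points at or
below baseline are excluded and counted; fewer than 3 usable points is an
error. A flagged two-point fallback (ln-ratio of first and last points)
exists for sparse records. On noiseless data the estimator is exact to
machine precision; note that for fast decays the excess C−B eventually
falls below the double-precision resolution of B itself, which bounds the
attainable accuracy (the tests therefore span a fixed number of
e-foldings).

The comparison helper reports the exact relative difference
100·(λ_PFT − λ_decay)/λ_decay and performs no rounding.

## Synthetic-data generator

The generator emulates the reference survey design: a 3-room dwelling
(13.2, 10.7 and 9.9 m² at 2.2 m ceiling → 29.04/23.54/21.78 m³), one
tracer per room with four dosers per room at measured 25 °C rates
(HxFBz 0.23, OFT 0.082, PFABz 0.015 mg/h per doser), 24-h sampling, and
the measured sampler calibrations (recoveries 0.40/0.72/0.84, sampling
rates 10.5/14.4/12.2 mL/min).

- Balanced flow fields: exhausts and inter-room flows drawn uniformly from
  a range (default 1–100 m³/h); infiltrations set by closure exactly,
  redrawing when a closure-implied infiltration would be negative.
- Concentration noise: multiplicative lognormal, mean-one, default CV 5%.
  No published noise magnitude exists for these samplers; 5% is this
  package's stated assumption of a well-run passive sampler and is the
  default study condition for the stochastic tests.
- Weights and CO₂: additive Gaussian (instrument-dominated).
- One scenario seed fans out to per-stream sub-seeds
  (`numpy.random.SeedSequence.spawn`), so enabling one noise stream never
  changes another's draws.

What passing the synthetic tests shows — and does not. They establish that
the estimator inverts its own physics exactly (round trips), that both
solver routes agree, that noise propagates at the expected magnitude, and
that the calibration algebra matches published constants. They do **not**
establish field accuracy: real rooms are imperfectly mixed, flows vary
within the day (window opening dominates), dosing rates drift with
temperature, and sampler noise may be non-lognormal. The generator also
deliberately omits occupant-behaviour schedules and auxiliary spaces
(closets, bathrooms) whose inclusion can shift room rates substantially —
reported field analyses note ~30% for a kitchen adjoining unmodelled
bathroom/lavatory volumes, which is not reproducible without those
volumes.

## Known limitations

- One tracer per zone only; over-determined multi-tracer designs and
  time-resolved estimation are out of scope.
- No transient dynamics: a survey that violates the >12 h equilibration
  assumption will be biased and the package cannot detect it.
- The raw weighting mode reproduces the traditional mixed-unit objective
  verbatim; results under heavy noise depend on that choice, which is why
  both modes are exposed.
- The decay method assumes a single well-mixed volume and an accurately
  known baseline.
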