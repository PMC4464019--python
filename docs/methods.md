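# Methods

This note documents the statistical conventions, numerical choices and
built-in models behind trajstat, and what its validation does and does not
establish.

## Sampling convention: zero-order hold

Trajectories produced by exact stochastic simulation are piecewise-constant
sample paths of a jump process: the state changes only at reaction events.
trajstat therefore samples a run at time t as its value at the latest
recorded event ≤ t (zero-order hold, right-continuous). Linear or spline
interpolation is deliberately not offered: it would fabricate fractional
molecule counts that the process never visits. Because independent runs
never share event times, every ensemble statistic first resamples each run
on a common uniform `TimeGrid` with this rule; resampling is idempotent
(resampling a resampled trajectory on the same grid is the identity), and a
finer grid never changes values at times shared with a coarser one.

Queries beyond a run's final recorded time return the last value with a
logged warning instead of failing. Runs stopped by event-count guards end at
different times, and a hard error would make an ensemble with one short run
unusable. The built-in simulator additionally records a final row holding
the state at `t_max` whenever the simulated horizon is reached, so its
trajectories cover the full interval and the hold-last rule only matters for
externally produced or guard-truncated data.

## Ensemble statistics

For an ensemble of n runs and a grid time t, the mean trace is the
arithmetic mean of the held samples and the standard deviation uses the
population convention (divide by n), consistent with the maximum-likelihood
variance; an `unbiased=True` switch divides by n − 1. The Gaussian fit
attached to density estimates is the closed-form MLE — sample mean and
biased variance — computed directly, never by iterative optimisation.

Density estimation histograms the cross-run sample {Xᵢ(t)}. Binning rules
("auto"):

- if all samples are integers to within 1e-9 **and** their span is at most
  400, bins of width 1 centred on integers over [min, max] — the natural
  quantisation for molecule counts (the span cap keeps pathological ranges,
  e.g. a run whose prey population exploded after predator extinction, from
  producing hundreds of thousands of unreadable unit bins);
- otherwise 30 equal-width bins over [min, max];
- if all samples coincide, a single bin of width 1 centred on the common
  value, with mass 1;
- a value exactly on an interior edge belongs to the bin on its right; the
  last bin is closed on both sides.

`normed=True` yields per-bin probability mass summing to 1 (the default
interpretation); a `density` flag divides by bin widths so the histogram
integrates to 1; `normed=False` returns raw counts. Multi-time densities
resolve one shared set of edges over the union of samples so bars are
comparable across times.

The empirical master-equation estimate resamples every run on a uniform
grid over [start, stop] (default 50 points), resolves one shared set of
state bins from the global extrema over all runs **and** all grid points,
and stacks the mass-normalised per-time histograms into a (time × state)
matrix. Every row sums to 1 by construction; the matrix is the ensemble
estimate of the master-equation solution P(x, t) and is rendered as a
heatmap (time horizontal, state vertical, fixed viridis colour map anchored
at [0, max mass]) or a 3-D surface.

## Built-in models and the simulator

The Gillespie direct method draws the waiting time from Exponential(a₀)
(a₀ = Σ aⱼ(x)) and picks channel j with probability aⱼ/a₀. Uniform variates
are consumed in a fixed order (drawn in batches of 8192 for speed), so equal
seeds give bit-identical trajectories. Per-run seeds derive from the master
seed through `SeedSequence(entropy=seed, spawn_key=(run,))`, making
ensembles reproducible regardless of generation order. An event-count guard
(default 10⁶) bounds runs whose populations explode.

- **Lotka-Volterra** (prey birth k₁·prey; predation k₂·prey·pred; predator
  death k₃·pred). Defaults k₁ = k₃ = 0.4, k₂ = 0.004, initial state
  (100, 100): the deterministic equilibrium is (k₃/k₂, k₁/k₂) = (100, 100)
  with period 2π/√(k₁k₃) ≈ 16 time units. Starting on the equilibrium,
  demographic noise drives oscillations of growing amplitude while both
  species persist beyond t = 100 in most runs (89/100 under the default
  seed derivation) — chosen once, by simulation, as a sustainable-but-noisy
  regime. In runs where predators go extinct, prey grow exponentially until
  the event guard trips; these rare runs are kept (they are real model
  behaviour) and dominate the global prey maximum.
- **Immigration-death** (influx k, per-capita death μ): from X(0) = 0 the
  transient law is Poisson((k/μ)(1 − e^(−μt))), stationary mean k/μ.
- **Pure death**: X(t) ~ Binomial(n₀, e^(−μt)) exactly.

The two birth-death models exist because their transient laws are exact
closed forms: comparing estimated densities against them in total variation
validates the entire pipeline (simulation, hold sampling, binning,
normalisation) at once. Mass-action models can also be declared in a small
YAML config (species, initial counts, reactions with rates and
reactant/product stoichiometries); propensities use the stochastic
convention (falling factorial over m! for m identical reactants).

## What the synthetic data does and does not show

The generator emulates well-mixed mass-action kinetics with exact
event-driven sampling. It does not emulate measurement noise, irregular or
censored observation times, non-Markovian dynamics, or spatial structure.
Passing validation therefore shows the statistics are computed correctly
for piecewise-constant jump trajectories; it does not certify behaviour on
smoothed or noisy experimental traces, where the zero-order-hold convention
is itself an approximation.

## I/O conventions

Delimited text: first column time, one file per run, `#` comments skipped.
Delimiter auto-detection tries tab, comma, semicolon, then whitespace on
the first data line; a first line with any non-numeric token is a header;
explicit `col_names` (first entry = time) override both. Floats are written
with 17 significant digits, so text and SBRML round-trips are exact for
double precision (parsing uses round-trip float conversion). Dataset
loading is process-parallel with one task per file and a deterministic
merge by sorted filename — the tested contract is bit-identical results for
every worker count, not the mechanism.

SBRML support covers a minimal time-course subset modelled on the standard's
layout: `operation/result/resultComponent`, each component carrying a
`dimensionDescription` (time index plus per-species value columns) and a
`dimension` of indexed tuples. Any other layout is rejected with an error
naming the offending element rather than half-parsed.

The result cache keys on a SHA-256 hash of the input data content (array
bytes, names) plus every statistic parameter, so renaming or touching files
never serves stale results and any data edit forces recomputation. Entries
are pickles in a dot-directory, size-capped (default 256 MiB) with
LRU eviction; a corrupt entry triggers a warning and a transparent
recompute, never a wrong answer.

## Reports

A report config is declarative YAML (dataset source or simulation recipe,
ordered analysis steps, output directory). All steps are validated before
any execution; a failure aborts with the step named, retaining partial
outputs and a MANIFEST marked `INCOMPLETE`. The run log records every
resolved parameter, dataset size, per-variable extrema and requested
Gaussian-fit parameters, so a run is reproducible from the log alone.
Executable scripts were rejected as a config format: batch reports should
be data, not code, and the Python API remains available for scripting.

## Problem sizes used in validation

The stochastic validation uses 2000-run ensembles for the analytic-law
recovery checks (total-variation bound 0.05, comfortably above the
Monte-Carlo noise floor at that size) and a 100-run predator-prey dataset
(horizon t = 120, event guard 3·10⁵) for the end-to-end report — sizes
chosen to exercise every code path at a scale a laptop reproduces in
seconds.

## Known limitations

- No kernel density estimation or multivariate joint densities; histograms
  only, per variable.
- The master equation is *estimated* from ensembles, never integrated
  numerically; no moment closure.
- No tau-leaping, delays or hybrid simulation; exact SSA only.
- SBRML coverage is the time-course subset described above; SED-ML and
  model-definition formats (SBML) are out of scope.
- Loading is in-memory; datasets larger than RAM are not streamed.
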