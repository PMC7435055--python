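# Methods

## Scientific setting

`restifit` analyzes single-cell photodamage–repair experiments in
gastric organoids.  After a high-power laser kills one cell, time-lapse
microscopy yields three trajectories per organoid: GFP-actin intensity
in the neighbors of the damage site (RLU, baseline-normalized),
damaged area (μm²), and the distance of the dead cell's nucleus from
the damage site (μm).  The package reduces each organoid to a vector of
13 static model parameters, compares treatment groups to controls, and
mines the pooled feature table with PCA and random-forest regression.

## The hybrid models

Each channel is an independent one-variable process; discrete timing
events switch rate terms on and off (a hybrid ODE).

**Actin** — three regimes:

- `[0, t_min]`:   dAct/dt = −act_depoly1 · (Act − act_min)
- `[t_min, t_max]`: dAct/dt = act_poly · (act_max − Act)
- `(t_max, ∞)`:   dAct/dt = −act_depoly2 · (Act − act_ss)

with Act(0) = act0 (default 1.0, baseline-normalized).  Each regime is a
linear relaxation, so the exact solution is piecewise exponential and
continuous at the switch times.  `act_max` is a *theoretical* attractor
the signal relaxes toward; the observed peak is below it whenever
`act_poly · (t_max − t_min)` is finite.  Likewise `act_min` is never
actually reached — the observed trajectory minimum sits slightly above
it.

**Damaged area** — dDA/dt = −k_repair · DA, so DA(t) = da0 · e^(−k_repair·t),
with da0 (default 100 μm²) the maximal damage at t = 0.  The equation
treats `k_repair` as a first-order rate (min⁻¹); reports echo the
conventional printed units (μm² min⁻¹).  The same convention applies to
`k_run` (μm min⁻¹ printed, min⁻¹ in the equation).

**Dead cell distance** — dDCD/dt = k_stay + k_run · (DCD_max − DCD), with
`k_run` off before the detachment event `t_detach`.  Before detachment
the cell drifts linearly at `k_stay`; afterwards it relaxes
exponentially toward the fixed point `DCD_max + k_stay/k_run`.  When
`k_run = 0` the fixed point is undefined and the solution remains the
linear drift; the code returns that limit rather than dividing by zero.

`integrate_numerically` solves the same ODEs with LSODA, restarting the
solver exactly at each switching event so events need not lie on grid
points.  It exists purely as an independent oracle for the closed
forms; the two agree to < 1e−6 over randomized valid parameter draws
(tested at rtol 1e−11).

## Feature extraction and fitting

Timing and level features are read directly from the data: `t_min` is
the time of the global minimum restricted to samples before the global
maximum, `t_max` the time of the global maximum after it (ties break to
the earliest occurrence), `act_min` the value at the minimum, and
`act_ss` the mean of the last 3 samples (window configurable).
`t_detach` comes from an exhaustive two-segment changepoint search:
every observed time τ is scored by the SSE of a straight line before τ
plus a saturating exponential after τ (the exponential's attractor is
profiled out in closed form, leaving a 1-D bounded search over the
rate), and the argmin is returned.  A best fit at the candidate-range
boundary, or no better than a single global line, flags the cell as
"never detached".

Rate constants and `act_max` are estimated by differential evolution
(population 30, up to 300 generations, seed 42 by default,
`scipy.optimize.differential_evolution` with L-BFGS-B polish) minimizing
the segment-wise SSE of the closed-form solutions.  Bounds: rates
[0, 50] min⁻¹; `act_max` within [observed peak, 5 × observed peak].

**Segment boundary ownership.**  The true regime switch almost never
coincides with a sample: the sample at the extracted minimum / peak /
changepoint generally still lies on the *previous* regime's curve.
Anchoring the next segment's fit on it therefore biases the fitted rate
(for the control-average cell at dt = 0.1 the rise-rate bias reaches
~20%).  Each segment is instead fit on the samples strictly after the
boundary, anchored at its first unambiguous observation, and the decay
attractors are estimated jointly with their rates (the directly
extracted `act_min`/`act_ss` remain the reported level features).  With
this convention the noiseless control-average round trip recovers every
rate to optimizer precision, and all 13 parameters to within
max(1%, one grid step) at dt = 0.1.

`k_stay` is the least-squares slope of the pre-detachment samples
(clipped at 0); `k_repair` pins da0 to the first observation and fits
the single rate (on noiseless data it coincides with the log-linear
regression slope to < 1e−4, an independent analytic cross-check kept in
the tests).  Channels are never fitted jointly — the three processes
are modeled as independent.

Failures degrade gracefully: non-conforming trajectories (no interior
minimum/maximum), too-short segments, or invalid values flag the
feature vector and leave the affected fields missing; `fit_cohort`
keeps the row so downstream stages can drop it with a logged count.

## Treatment comparison

Per drug and parameter, %Δ = 100 · (mean_drug − mean_control) /
mean_control over the per-organoid fitted values (mean aggregator by
default, configurable; missing values excluded pairwise).  The chord
edge lists keep, per drug, the most-activated and most-inhibited
parameter (most-negative signed value, not largest magnitude), and per
parameter the strongest enhancing and inhibiting drug; single-direction
cases yield one edge.  No significance testing is attached to these
percent changes.

## Machine learning

PCA standardizes all 13 parameters (zero mean, unit variance) before
decomposition; constant columns are dropped with a warning.  The forest
stage predicts each of the five behavior parameters (`k_repair`,
`t_detach`, `k_stay`, `k_run`, `dcd_max`) from the eight actin
parameters on the pooled cohort, with a 75/25 train/validation split
(seeded), 100 trees, unlimited depth.  Gini importances are rescaled so
the top predictor scores 100.  Hyperparameters are pinned rather than
left to library defaults so results are stable across versions.

## Synthetic cohorts

The generator draws per-cell parameters independently from truncated
normals around the control-cohort mean ± SD table (lognormal available
for strictly positive rates); the distributional family of the real
cohort is unknown, truncated normal is the transparent default.
Structural order constraints (`t_min < t_max`,
`act_min ≤ act_ss ≤ act_max`, `act_min ≤ act0`) are enforced by
rejection resampling, which slightly shifts the post-rejection means of
the constrained parameters away from the configured values — recovery
tests therefore compare fitted cohorts to the *realized* ground-truth
draws, not to the configured means.  Treatments multiply their target
parameters; a preset panel ships with qualitative directions for the
study's drug panel (magnitudes illustrative).  Optional couplings
rewrite behavior parameters as `a + b·t_max + ε`, the generative
surrogate for the observed actin-timing/behavior correlations; the
planted-signal configuration sets the slope so the signal SD equals the
parameter's cohort SD with noise SD one third of it (3:1).

Observation noise is additive Gaussian per channel (defaults 0.05 RLU,
2 μm², 0.2 μm); area and distance are clipped at 0.  The default grid
is 0–20 min at 0.5 min; fitting-resolution studies use dt = 0.1.  The
generator does not emulate photobleaching, drift, segmentation error,
or non-Gaussian outliers, so passing recovery tests demonstrate
correctness of the estimation machinery under the model's own
assumptions, not robustness to real microscopy artifacts.

## Problem sizes and numerical choices

Test and acceptance workloads are sized for a laptop-class single CPU:
noiseless round trips use one control-average cell on a 201-point grid;
heterogeneous-cohort recovery uses 20 cells; Monte-Carlo noise studies
use 50 replicates (achieved baselines: detachment median |error|
0.05 min at σ = 0.2 μm; final actin decay rate median relative error
≈ 10% at σ = 0.05 RLU); the planted-signal forest cohort uses 150
cells.  Degenerate inputs are handled explicitly: zero rates produce
constant/linear closed forms; flat rise segments leave `(act_poly,
act_max)` on the zero-SSE degenerate edge (the predicted curve is flat
even though the pair is not identifiable); DE determinism is guaranteed
by the config seed.

## Known limitations

- The timing features inherit the grid resolution: `t_min`, `t_max`,
  `t_detach` are only identified to one sample interval, and extracted
  levels carry an O(dt) bias relative to the model attractors.
- Cells whose actin minimum occurs within the first two samples, or
  whose rise is too flat to produce an interior peak, cannot be fully
  featurized and are flagged; at coarse sampling this censors fast or
  weak responders.
- Percent-change chord edges are descriptive extremes without
  uncertainty estimates.
- Forest importances are impurity-based and shared between correlated
  predictors; duplicated information splits the score.
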