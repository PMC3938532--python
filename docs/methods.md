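# Methods

This note documents the models, the synthetic data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## The maxent model and its estimation

The model class is the log-linear (Gibbs) distribution over the background
sample, q_λ(x) ∝ exp(Σ_j λ_j f_j(x)). At β = 0 its maximum-likelihood fit is
exactly the maximum-entropy distribution whose feature expectations equal the
presence-sample means; with β > 0 each expectation is instead matched within
a box of half-width β_j — the usual guard against overfitting sparse presence
sets.

**Features.** All features are scaled to [0, 1] using the background min/max
of each variable, so a single regularization scale serves every class:
linear (the scaled variable), quadratic (its square), product (pairwise
products of scaled variables), and hinge (forward `clip((v−k)/(max−k),0,1)`
and reverse `clip((k−v)/(k−min),0,1)` ramps with knots at equally spaced
background quantiles, default 10 per variable). Classes are activated by
presence sample size — linear always, quadratic at ≥ 10, hinge at ≥ 15,
product at ≥ 80 — the conventional ladder for presence-only models, since the
exact published defaults of any particular implementation are not a contract
here. Feature specs are fitted on the background once and applied identically
to presence, background, and prediction points.

**Regularization.** β_j = r·s_j/√m with s_j the presence-sample standard
deviation of feature j, floored at 0.05 (5 % of the unit feature range) so
near-constant features are not left effectively unpenalized, and r a global
multiplier (default 1.0, exposed in config and logged).

**Optimizer.** Cyclic coordinate descent in a deterministic feature order.
Each coordinate takes a Newton step on the smooth part (gradient
p̄_j − E_q[f_j], curvature Var_q[f_j]) soft-thresholded by β_j, with a
halving backtracking guard so the penalized objective never decreases; the
background score vector and log Z are updated incrementally. Convergence
requires both a relative objective change below 1e-7 over a sweep and every
coordinate's KKT violation below 1e-7 — at β = 0 the KKT violation *is* the
moment-matching gap, which is how the fitter honours the defining constraint
to the tested 1e-5 rather than merely plateauing. The cap is 500 sweeps;
hitting it warns and returns the model (the fits in question are virtually
converged — observed terminal violations are ~1e-7).

Every accepted update appends (source variable, objective gain) to the fit
trace. Percent contribution sums the positive gains per variable and
normalizes to 100. Product features split their gain equally between their
two sources. Path attribution is order-dependent in principle; for correlated
predictors the split reflects who moved first, which is why the correlation
screen precedes fitting. A fully shrunk model (empty trace) reports uniform
contributions with a warning. Jackknife importance (refit without each
variable / with only it) is reported alongside, with both training gain and
AUC, because the two conventions circulate; with `jackknife_k = 0` the AUC
column is the training AUC (no extra CV refits), with k ≥ 2 it is the mean
k-fold test AUC.

**Outputs.** Raw probabilities normalize to 1 over the background. The
logistic output is c·raw/(1 + c·raw) with c = e^H, H the entropy of the raw
distribution over the background; the uniform model therefore scores exactly
0.5 everywhere. Training gain is the mean presence log-likelihood improvement
over uniform: mean(Σλf − log Z) + log n_bg.

**Cross-validation.** Presences are shuffled once per run seed and split into
k folds differing in size by at most one (default k = 25, auto-lowered with a
warning when presences are fewer). Test AUC is test presences versus the full
background — with presence-only data there are no absences to hold out. The
mean prediction raster is the cellwise mean of the fold models' logistic
outputs. The MTP threshold is the mean over folds of each fold's minimum
training-presence score; binarizing a fold at its *own* minimum keeps 100 %
of that fold's training presences in habitat, exactly, and that property is
asserted.

**Discrimination classes.** Strict Hosmer–Lemeshow bins: ≤ 0.5 no better than
random, (0.5, 0.7) poor, [0.7, 0.8) acceptable, [0.8, 0.9) excellent, ≥ 0.9
outstanding. Published usage sometimes rounds an AUC of 0.69 up into
"acceptable"; the bins here are kept strict and any such discrepancy is
attributed to rounding.

## Background construction

The sightings' Gaussian KDE (Scott's rule per axis, n^(−1/6)·sd, scalar
override available) is evaluated at cell centers, masked to sea, and
normalized to sum 1. Volume contours take cells in descending density order
(ties broken row-major) until the cumulative density reaches q/100; the 100 %
contour is every positive-density cell, and the masks nest by construction.
Background points are allocated equally across the five strata (remainder to
the widest), drawn uniformly with replacement *within* each mask, and placed
at cell centers — the environment is cell-valued, so sub-cell placement would
add nothing. Equal shares over nested masks over-weight high-density areas,
which is the target-group-background intent; per-stratum counts are logged so
the choice is auditable.

## The synthetic world

The generator produces the statistical structure the analysis assumes, with
known truth:

- **Grid**: abstract equal-area plane, default 45×60 cells of 4 length units
  (the analysis resolution); the hotspot index uses a 5× coarser grid.
- **Environment**: three dynamic fields (temperature-, chlorophyll-, and
  salinity-like) built as unit-variance Gaussian random fields
  (`gaussian_filter` on white noise, smoothness σ = 4 cells) plus a
  deterministic gradient — one per field along x, y, and the diagonal so the
  fields are not mutually collinear — plus a sinusoidal seasonal cycle with
  per-field amplitude and phase across the 12 monthly layers.
- **Bathymetry**: depth grows with distance from a contiguous wiggling coast
  (power 1.2, multiplicative smooth noise), guaranteed to cross both the
  30 m and 200 m levels so shelf-break derivatives exist.
- **Truth**: a log-linear probability surface over sea cells on min-max
  scaled predictors, the same family the fitter estimates; coefficients of
  magnitude 2.5–4 give strong but not degenerate niches.
- **Observer bias**: a single Gaussian bump ("port") multiplying the truth
  when sightings are drawn — the simplest field that reproduces the
  clustered-sampling problem the contour background corrects.
- **Sightings**: default 150 per target and season for the main targets
  (12–60 for the deliberately sparse ones, including a turtle with winter
  N = 2 and spring N = 1 to exercise the insufficient-sample path); a 6 %
  defect rate (sea state > 3, blank family, out-of-bounds, bad dates) feeds
  the QC stage.
- **Strandings**: 240 records along coastal cells with configured cause
  probabilities (55 % undetermined by default), zone weights, 25 % live
  fraction, years 2002–2011.

What it does **not** emulate: real coastline geometry, satellite noise and
cloud gaps, species-specific movement or aggregation behaviour, inter-annual
trends, or taxonomic misidentification. Passing tests therefore demonstrate
that the machinery is correct and that bias-matched background recovers a
known niche under clustered sampling — not that any particular real species'
map would be accurate.

## Numerical and design choices

- **Slope** uses Horn's 3×3 stencil (the standard GIS "slope" operator), in
  degrees, with replicate edge padding; NaN cells are filled from their
  nearest data cell for the stencil and re-masked, so coastal slopes are
  defined without inventing land bathymetry.
- **Isobath cells** are sea cells with depth ≥ level that 4-neighbour a
  shallower cell — a concrete, testable discretization of a contour.
- **Distances** are exact Euclidean center-to-center distances
  (`distance_transform_edt`), no geodesic correction (the plane is abstract
  and equal-area by construction).
- **Correlation screen**: of each offending pair (|r| ≥ 0.7 default), the
  member with the larger mean |r| against all other kept variables is
  dropped; ties fall to the later column. Zero-variance variables are dropped
  up front (r undefined).
- **Cells are half-open** ([x0, x0+Δ) × (y0−Δ, y0]), so boundary points land
  in exactly one cell; zone polygon ties go to the first zone in file order.
- **Plankton occurrence surfaces** are kernel intensities rescaled to max 1 —
  a synthetic stand-in for interpolated probability-of-occurrence products,
  flagged as such in layer provenance.
- **Determinism**: every stage draws from generators seeded from the run
  seed; reports carry no timestamps, floats are rounded to 10 decimals (JSON)
  or written with `%.10g` (CSV), and the config hash excludes output paths,
  so identical (config, seed) runs are byte-identical wherever they land.

## Problem sizes

The analysis scripts run the full chain at 45×60 cells, 2,500 background
points over the five contour strata, 5-fold cross-validation, and 5 hinge
knots per variable — about a minute on one core for 17 seasonal models, with
every mechanism of the full-scale protocol intact. The library defaults
(10,000 background points, 25 folds, 10 knots) match the full protocol. The
test suite uses a 30×40 grid: resolution matters scientifically, not just
computationally — on substantially coarser grids the KDE volume contours
cannot resolve the observer-bias bump, residual bias leaks into
gradient-aligned predictors, and the closed-loop recovery of the truth
variable degrades. 30×40 is the smallest grid at which the mechanism is
preserved.

## Known limitations

- Percent contributions inherit the path-dependence of gain attribution;
  they are comparable across runs (deterministic order) but, for strongly
  correlated predictors, not a causal decomposition.
- The KDE bandwidth and the equal allocation of background points across
  contour strata are defensible defaults, not estimated quantities; both are
  configurable and logged.
- Presence-vs-background AUC saturates well below 1 for wide-ranging species
  by construction; absolute AUC values should be read against that ceiling,
  which is why discrimination classes, gains, and contribution patterns are
  reported alongside.
- The strandings trends are effort-uncorrected; without an effort covariate
  no correction is attempted, and the tables say so.
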