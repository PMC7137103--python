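# Methods

This note records the model, the numerical choices and the design decisions
behind `xtalscale`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Scaling target

Each observation carries a multiplicative inverse scale g, and the model
parameters are estimated by minimizing

    Φ(p) = Σ_hl w_hl (I_hl − g_hl(p) ⟨I_h⟩)² + Σ_i c_i (p_i − p0_i)²

The group best estimate ⟨I_h⟩ = Σ w g I / Σ w g² is itself the least-squares
minimizer, so it is eliminated analytically: it is re-evaluated at every
objective evaluation, making Φ a function of the model parameters alone.
By the envelope theorem the analytic gradient then needs no ∂⟨I_h⟩/∂p term,
which both the quasi-Newton and the full-matrix stage rely on.  Groups of
size one contribute nothing to the data term (their mean fits exactly);
with a reference data set ⟨I_h⟩ is fixed to the reference values instead and
singletons do contribute.  Weights w = 1/σ′² are frozen at the start of
each minimization block and refreshed when the error model updates σ′.

### Gauge fixing

The data term is invariant under g → αg, ⟨I_h⟩ → ⟨I_h⟩/α.  After each
minimization block the gauge is pinned by rescaling so the first sweep's
scale-component parameters have mean 1 (for the KB model, k = 1 for the
first sweep); this is a pure reparameterization and leaves Φ unchanged,
which is asserted in the tests.  Two further near-degeneracies are worth
knowing about:

* a constant offset of the relative B factor is absorbed exactly by the
  group means; the weak restraint of the B parameters towards zero selects
  the mean-zero representative.  Consequently the synthetic generator's
  ground-truth B(t) is defined mean-zero over the sweep, so recovered and
  generated scales are comparable without an arbitrary offset.
* with constant resolution across all observations, the KB model's k and B
  columns are collinear; the full-matrix stage detects a (near-)singular
  normal matrix by its eigenvalue spread (ratio < 1e-12), omits the
  covariance and reports status "degenerate" rather than inverting noise.

### Minimization

The bulk of the optimization uses L-BFGS (scipy) with the analytic
gradient, up to 100 iterations, relative-Φ tolerance 1e-6.  The final cycle
is a Levenberg–Marquardt solve of the damped normal equations with ⟨I_h⟩
held fixed within each outer iteration: λ starts at 1e-3, ×10 on a rejected
step, ÷10 on acceptance, with Marquardt diagonal scaling.  Restraints enter
as extra residual rows √c·(p − p0) and are therefore part of the normal
matrix and of the reported covariance.  Parameter uncertainties propagate
to the scales as var g = J Cov Jᵀ per row, and to the corrected intensities
by first-order error propagation assuming independence:
σ²(I/g) = σ′²/g² + I²·var g/g⁴ (the propagation formula is this package's
choice; only the fact of propagation, not the formula, is standard).
A trial point driving any g ≤ 0 is rejected (Φ = ∞), which is the
minimization guard for non-positive scales.

## Model components

* **Smooth 1D components** (scale, decay): n = ceil(width/spacing) + 2
  parameters at unit spacing in the adjusted coordinate, one padding node
  beyond each end, nodes centred on the sweep.  The value is a normalized
  Gaussian-weighted sum of the nearest three parameters with weight
  exp(−Δx²/V), V = 0.5 in spacing units.  Defaults: 15° spacing for the
  scale, 20° for the decay — reproducing 26 and 20 parameters for a 360°
  sweep; sweeps narrower than 30° shrink the spacing to width/10 (floor
  1°), while an explicitly finer spacing is honoured as given.  The decay
  evaluates exp(B(t)/2d²) and its B parameters are restrained towards zero
  with weight 1e-3.
* **Absorption surface**: 1 + Σ P_lm · ½[Y_lm(s0c) + Y_lm(s1c)] with real
  orthonormal spherical harmonics (no Condon–Shortley phase), l = 1..4 by
  default (24 coefficients).  Odd-l terms are retained (they capture e.g.
  crystal miscentering).  The exact symmetrization over the two beam
  directions is a design choice: the ½-sum makes the surface symmetric
  under swapping the directions.  Coefficients are restrained towards zero
  (surface towards 1) with weight 1e6 — strong enough to keep the surface
  near 1 where the data do not demand otherwise, weak relative to the data
  term of a typical run (the tests confirm a 5% synthetic surface is still
  recovered).
* **Array grids**: separable Gaussian smoothing over the nearest three
  nodes per dimension, coordinates clamped to the grid hull, no padding.
  Default grids: decay = (rotation node per 15°) × 10 resolution nodes,
  absorption = 5 × 5 detector × (rotation node per 18°) — 240 and 500
  parameters at 360°; detector modulation (5 × 5) exists but is off by
  default, as it mostly duplicates corrections already applied at
  integration on modern photon-counting detectors and correlates with the
  other components.

All components are multiplicative; identity initialization (C = 1, B = 0,
P = 0, grid = 1) gives g ≡ 1 exactly.

## Symmetry handling

Space-group operations, systematic absences and d-spacings come from gemmi.
The canonical symmetry-unique index is the lexicographically greatest
member of the orbit under the point group, with Friedel mates merged unless
anomalous separation is requested; this convention is idempotent, fully
vectorizable, and is also used when enumerating the theoretically possible
unique reflections for completeness (so observed and possible counts are
directly comparable — the enumeration is validated against gemmi's
reciprocal-space ASU in the tests).

## Error model

σ′² = a²(σ² + (bI)²), applied with I the scaled intensity (equivalently,
in raw units, with the raw intensity — the two differ only by the factor g
carried by both numerator and denominator of δ).  The normalized deviations

    δ_hl = sqrt((n−1)/n) · (I_hl/g_hl − ⟨I_h⟩₋l) / (σ′_hl/g_hl)

use the leave-one-out weighted group mean, are defined only for groups of
size ≥ 2, and should be standard normal when the model is right; no
mean-variance term is added to the denominator beyond the (n−1)/n factor.
Estimation alternates (from a = 1.0, b = 0.02): the slope of the central
section (25th–75th percentile, Blom order statistics, OLS) of the normal
probability plot gives the consistent a for a fixed b exactly — δ scales as
1/a — so the a condition is profiled out inside a bounded golden-section
search on b ∈ [0, 0.5] that drives the sd of δ in 10 equal-count intensity
bins (≥ 100 deviations each, pooled otherwise) to 1.  Convergence when both
parameters move < 1e-4; fewer than 500 usable deviations returns the
identity model with a warning.  ISa = 1/(ab).  Group-mean weights are
frozen for the duration of a refinement.

## Outliers and intensity combination

Outliers are tested per symmetry group against the leave-one-out weighted
mean: |I/g − m₋l| / (σ²_obs + σ²(m₋l))^½ > z (default 6).  Rejection is
worst-first within each group and re-tested, since a gross outlier drags
the leave-one-out means of the good members far enough to flag the whole
group in a single pass.  Size-2 groups use the mutual-difference test and
flag both members (the deviant one cannot be attributed; configurable
off); singletons are never flagged.  Every round re-tests previously
flagged observations against the updated model.

Profile/summation combination uses the smooth crossover
w = 1/(1 + (I_raw/I_mid)³) on the raw summation intensity (clamped at 0
for negative measurements), combining variances with the same weights
under an independence assumption.  Eight logarithmically spaced I_mid
values spanning [I_min + 1, I_max] plus the two pure modes are scored by
R_meas on the currently scaled data; ties break towards profile.

## Merging statistics

R metrics use the unweighted group mean of corrected intensities (the
convention of the published definitions); the merged output uses the
inverse-variance weighted mean — both conventions are stated in the
report.  CC1/2 uses the σ–τ estimator per resolution bin:
σ_y² is the variance of the merged intensities across unique reflections,
σ_ε² the mean per-group error variance of a half-data-set mean (unbiased
within-group variance divided by n/2), and
CC1/2 = (σ_y² − ½σ_ε²)/(σ_y² + ½σ_ε²); the overall value is the
group-count-weighted average over bins (observation-count weighting would
differ only for very uneven multiplicity).  Binning is equal-count on
1/d²: 20 bins for reports, 10 for ΔCC1/2 and error-model work.

ΔCC1/2 for subset i is CC1/2 − CC1/2(−i) with bins held fixed.  The
exclusion cut (default 4σ) is evaluated for each subset against the
mean and sd of the *other* subsets' values: with a small partition a
grossly discordant subset would otherwise inflate the spread enough to
hide itself (in a partition of 10, no point can ever be 4 sample-sd below
a mean that includes it); for the large partitions the cut is intended
for (hundreds of image groups) the two versions coincide.  Filtering
cycles alternate scaling (without the full-matrix stage) and exclusion
until no subset is cut, a cycle limit (10), a completeness floor (90%) or
a removal budget (10% of observations) stops them, then a final
full-matrix scaling pass runs.

## Selection and free sets

Model optimization uses a subset of symmetry groups satisfying two
thresholds — at least 2000 groups *and* 50 000 reflections — chosen
randomly for single sweeps.  For multi-sweep data the quasi-random
algorithm first runs a greedy connectivity pass per resolution bin (10
equal-count bins): repeatedly pick, among groups observed in the currently
least-populated sweep, the one spanning the most sweeps (ties: larger
group, then lower group index — deterministic runs), until each sweep
reaches its share (min_reflections / n_sweeps, split evenly over bins) or
runs out; random per-sweep and across-sweep augmentation then tops up to
the global thresholds with an even split of the remaining budget.

Free sets are whole symmetry groups dealt into round(1/fraction) folds
(default 10% → 10 folds) so all equivalents of a reflection share a fold;
models are fitted on the work set only, applied to everything, and work
and free R_meas and CC1/2 are averaged over folds (R_meas preferred over
R_p.i.m. because it is multiplicity-independent and the two sets have
different multiplicities).

## Synthetic data

The generator draws unique reflections from a real lattice (cell + space
group via the same enumeration used for completeness), exponential
(Wilson-like) true intensities with mean ∝ exp(−B_wilson/2d²), per-sweep
smooth sinusoidal scale variation, a linear mean-zero relative-B drift, a
spherical-harmonic absorption surface, counting-noise variances
(σ₀² = I + background) and optional variance inflation by (a, b) — the
reported variances stay at σ₀², so the generated data violate their own
error bars exactly as the two-parameter model assumes.  Geometry: the
reverse incident beam rotates with φ about the lab x axis into the crystal
frame; the scattered beam lies on the 2θ(d) cone at a random azimuth
(λ = 1 Å).  Observed intensities are g_true · I_true plus noise, so
dividing by the recovered g reproduces I_true.  Default conditions for
recovery tests: multiplicity 5, ⟨I/σ⟩ ≈ 20–25, ±20% scale amplitude, 3 Å²
decay, 5% absorption — a well-exposed, well-behaved sweep.

What the generator does **not** emulate: profile-fitting correlations
between neighbouring observations, non-Gaussian and non-stationary
backgrounds, detector-module systematics, partiality, unit-cell drift and
genuine radiation-damage chemistry.  Passing recovery tests therefore
demonstrate the estimator's correctness and calibration under its own
assumptions, not end-to-end performance on real beamline data (the
original evaluation of this family of algorithms used real multi-crystal
data sets that are out of desk-scale reach).  The filter fixture provides
two distortion modes: a smooth resolution-dependent multiplicative factor
(largely absorbable by a per-sweep B factor — visible to a direct ΔCC1/2
analysis but intentionally correctable by scaling) and intensity
scrambling (non-isomorphism no multiplicative model can absorb, which is
what the scale-and-filter cycle must catch).

## Problem sizes and determinism

The shipped tests and the acceptance script run simulations of roughly
3 000–25 000 observations (unique-reflection sets of ~600–5 000 from small
orthorhombic cells), sizes at which every stage — including the
full-matrix cycle with its dense normal-matrix solve — completes in
seconds while leaving parameter-recovery noise well below the asserted
tolerances.  All stochastic steps (generation, selection, free-set
dealing) take explicit integer seeds; regeneration from the same seed is
bit-identical.

## Known limitations

* Dense normal-matrix solve in the full-matrix stage: fine up to a few
  thousand parameters, not intended for pathological many-sweep runs with
  full-matrix enabled on all parameters at once.
* A single error model per scaling run (no per-sweep a, b).
* No anomalous half-set statistics or amplitude (French–Wilson-style)
  conversion; merged output is intensities.
* Completeness requires a unit cell; without one it is omitted from
  reports.
* The deltaCC1/2 filter is a semi-automated exploration tool; the stopping
  rules are deliberately conservative and user-adjustable rather than
  optimal for every data pathology.
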