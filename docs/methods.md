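# Methods

This note documents the models and procedures implemented in `hismatch`,
the defaults and why they were chosen, what the synthetic simulator does
and does not emulate, and the numerical choices that affect
reproducibility.

## Parameter space and frames

All sampling, emulation and implausibility scoring happen on the unit
hypercube `[0, 1]^d`; natural units appear only at the simulator boundary
and in reports. This makes GP length-scales comparable across parameters
and keeps quasi-random designs uniform. The default 14-dimensional space
is nine statistical-shape-model mode weights followed by five EP
parameters (fibre angle, FEC layer height, CV, k_xf, k_FEC) with their
physiological ranges. Mode weights default to [−3, 3], read as SD units of
a shape mode; the tight, cohort-specific intervals depend on the anatomical
atlas in use, so the bounds are a configuration field rather than a
constant.

## Gaussian-process emulators

One univariate exact GP per biomarker:

* **Mean**: linear, `m(x) = β₀ + Σ βᵢxᵢ`. Given the kernel hyperparameters,
  `(β₀, β)` maximizing the marginal likelihood have a closed generalized
  least-squares form, so they are profiled out exactly at every optimizer
  step rather than optimized numerically.
* **Kernel**: ARD squared-exponential
  `σ_f² exp(−Σ (xᵢ−xᵢ′)²/(2δᵢ²))`. Other denominator conventions merely
  reparameterize δ.
* **Noise**: iid Gaussian with variance σ_n, fitted by default. Downstream
  predictive variance (and hence implausibility) includes σ_n: the noise
  term is part of the emulator's predictive uncertainty. For deterministic
  simulators `noise_free=True` pins σ_n to exactly 0 so the emulator
  interpolates with zero variance at training points; a separate
  factorization jitter (1e−10, escalated 1e−10 → 1e−8 → 1e−6 on Cholesky
  failure) is used for numerical stability only and is never added to the
  reported variance.
* **Optimization**: L-BFGS-B over log-hyperparameters with analytic
  gradients (the envelope theorem covers the profiled mean). Default 10
  restarts: one from a fixed sensible point (δ = 0.5 cube widths,
  σ_f = 1 SD, σ_n = 1e−2 SD²), the rest from a Latin hypercube in
  log-space. Box bounds δ ∈ [1e−2, 1e2], σ_f ∈ [1e−3, 1e3],
  σ_n ∈ [1e−8, 4] (standardized units) keep the search away from
  degenerate plateaus. Outputs are standardized to zero mean / unit
  variance internally for optimizer conditioning and de-standardized on
  prediction; reported hyperparameters are on the natural output scale.
* **Validation**: R² = 1 − SS_res/SS_tot and the independent standard
  error, ISE = % of held-out points with |mean − y| < 2·SD strictly. The
  strict inequality means a degenerate SD of exactly zero counts as a
  failure even with an exact mean; this boundary convention is asserted in
  tests.

A fixed-hyperparameter constructor (`from_hyperparameters`) bypasses
optimization and standardization; it is what the closed-form and
dense-linear-algebra oracle tests, and the coverage-calibration check, are
built on.

## Implausibility and NROY bookkeeping

`I(x) = maxᵢ |E[fᵢ(x)] − μᵢ| / sqrt(Var[fᵢ(x)] + σᵢ²)` — the square-root
form of the squared statistic; max is monotone so the two orderings agree,
and the square root is numerically safer. Points are kept strictly below
the threshold (the boundary has measure zero; the choice is stated for
bit-reproducibility).

**Cumulative membership.** A point is NROY after wave k iff it passes
*every* wave j ≤ k at that wave's threshold. Later emulators therefore
never re-admit previously excluded points, which guarantees the NROY
fraction is non-increasing in the wave index — standard history-matching
practice, and asserted as an exact invariant in the tests.

**NROY size estimation.** Monte-Carlo fraction over a fixed unscrambled
Sobol' reference set drawn once at run start (default 10,000 points;
candidate sets skip past it in the sequence so the two never alias).
Fixing the set makes NROY sizes and all cross-run overlap/match statistics
well-defined comparisons on identical point sets.

**Wave schedule.** Wave 1 cuts the candidate set with the bank trained on
the initial Latin hypercube design and runs no additional simulations;
each later wave simulates a batch inside the current NROY region, refits
on everything accumulated, and re-cuts. This matches the intended
simulation accounting (an initial design, then `n_per_wave` per subsequent
wave). Batches are chosen by greedy maximin (farthest-point) selection so
they stay space-filling inside NROY; the starting point is seed-chosen.

**Cloud resampling.** Later waves need candidates inside the current NROY
region. Each surviving point spawns offspring from a multivariate normal
centred on it; the scale starts at 0.05 cube widths and grows linearly
with the round index ("expanding" rounds), so the boundary between NROY
and ruled-out space is probed. Offspring outside the unit cube or failing
the membership predicate are rejected; a round cap (50) bounds the search,
returning fewer points with a warning when the quota cannot be filled.
The scale, offspring count and cap are configurable; the defaults are this
package's choices since no canonical values exist.

**Diagnostics.** The variance quotient `VQ(x) = maxᵢ Var[fᵢ(x)]/σᵢ²`
(worst biomarker) is summarized by its max and median over NROY reference
points; VQ ≫ 1 means emulator uncertainty dominates the data uncertainty
and more simulations would help. Mask agreement between two runs is
reported both over the whole space (% equal status) and over one run's
NROY (% also kept by the other); the latter is flagged not-applicable for
an empty NROY rather than reported as 0/0.

## Reuse and uncertainty sensitivity

Reuse is a single implausibility pass of the reference set under a donor's
trained bank with the recipient's targets at the final threshold (3.0
default) — zero simulator calls, which tests assert via a call counter.
Targets derived from deterministic simulations use `σᵢ = c·μᵢ`; c = 0.10
is the default ("high uncertainty") and c = 0.05 the sensitivity setting.
The sensitivity comparison can either re-run the pipeline per c (the full
protocol; containment not guaranteed because banks differ) or re-score one
fixed set of banks (in which case NROY(c=0.05) ⊆ NROY(c=0.10) exactly —
asserted as an invariant).

## Synthetic cohort

The packaged simulator maps the 14 unit-cube inputs to four biomarkers
through smooth closed forms: a heart-size factor dominated by the leading
shape modes (mirroring PCA variance ordering, with one mode interaction),
activation time ∝ size/CV modulated by the cross-fibre ratio and the FEC
velocity ratio, an endocardial activation fraction bounded in [0.20,
0.50] so TAT_LV_endo < TAT always, LV mass as a power of the size factor
and a linear anatomical dimension. TAT stays within [50, 125] ms over the
cube, bracketing the literature target 76.4 ± 8.2 ms.

What it deliberately is *not*: a numerical match to finite-element
reaction-eikonal outputs. It has no mesh, no fibre architecture, no
discretization error, and its outputs are noise-free and far smoother than
real simulations. Passing tests therefore demonstrate the calibration
machinery (exact GP algebra, monotone NROY logic, reuse accounting,
determinism) — not that a real EP model would yield the same NROY
percentages. One visible consequence: with four smooth biomarkers at
c = 0.10 the synthetic NROY regions stay large (tens of percent), whereas
rougher simulators and tighter uncertainties cut much harder.

Synthetic ground-truth points are drawn from [0.15, 0.85]^14 to keep them
away from the box boundary, where GP extrapolation is least reliable —
mirroring the fact that real subjects are interior members of their
cohort. ℓ1-farthest subject selection supports both input-space distance
(unit frame) and biomarker-space distance (z-scored across the cohort so
units do not dominate), with ties broken to the smallest id.

## Problem sizes used in tests and the acceptance script

Full-scale defaults (280/70/88 initial split, 140 per wave, 10,000
candidates) are the configured defaults, but the shipped test suite and
`scripts/acceptance.py` run a reduced configuration — 80/20/10 initial
split, 40 per wave, 2000 candidate and reference points, 3 restarts —
chosen so a complete 3-wave calibration takes seconds while keeping
n ≫ d + 2 training points per fit. The 80/20/10 split keeps the same
roughly 4:1:0.5 proportions as the full design. Recovery sweeps use 20
subjects in the tests and 10 in the acceptance script.

## Numerical choices

* All randomness flows from a single integer seed per run; derived seeds
  (per-biomarker fits, batch selection, cloud rounds) are fixed offsets of
  it, so identical configuration reproduces byte-identical ledgers, banks
  and reports (hash-compared in tests).
* Sobol' sequences are unscrambled (first point at the origin) so designs
  are reproducible across platforms without seed bookkeeping.
* Out-of-bounds checks at the natural↔unit boundary use a 1e−12 relative
  tolerance and name the offending parameter.
* Bank persistence stores hyperparameters in JSON at full repr precision
  and training matrices as CSV; round-trips are exact for hyperparameters
  and reproduce predictions to float precision.
* Frequency maps bin the NROY reference points over each parameter's full
  natural range (20 equal-width bins by default); proportions sum to 1 per
  parameter by construction.

## Limitations

* Emulators are independent per biomarker; correlated multi-output GPs are
  out of scope, so joint-biomarker implausibility is conservative.
* The wave schedule is fixed (no convergence-based threshold adaptation).
* No MCMC posterior or model comparison: history matching bounds the
  plausible region, it does not weight points within it.
* The cloud technique's escalation schedule is heuristic; very thin NROY
  regions can exhaust the round cap and return short candidate sets
  (flagged with a warning).
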