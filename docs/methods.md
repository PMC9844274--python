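# Methods

This note documents the models, default parameters, numerical choices and
known limitations of the package. Everything quantitative stated here is
recomputed by the test suite or by `scripts/acceptance.py`; nothing is
asserted from memory.

## Stimulus construction

**Value grids.** Lengths: 44–116 px in 4 px steps (19 values).
Orientations: 4.5°–85.5° clockwise from vertical in 4.5° steps (19 values).
Orientations are treated linearly, not circularly: the full range spans
81° < 90°, so angular wrap-around can never bind.

**Factorial designs.** Length task: relevant means {56, 68, 80, 92, 104} px,
relevant SDs {8, 12} px, irrelevant orientation means {31.5, 45, 58.5}°,
irrelevant SDs {9, 13.5}°. Orientation task: relevant means
{18, 31.5, 45, 58.5, 72}°, SDs {9, 13.5}°, irrelevant length means
{68, 80, 92} px, SDs {8, 12} px. Crossing with 2 repetitions gives 120
trials per task. The relevant means double as the 5-AFC probe values, so
errors live on {0, 1, 2, 3, 4} probe spacings and "correct" means zero
error. Trial order is one fixed seeded shuffle, identical for every
simulated participant.

**Realizing an ensemble.** Twelve grid values must hit the target mean
exactly and the target SD approximately. On the index lattice this is an
integer problem: the sum of indices is fixed by the mean (all design means
are representable; the package verifies this at call time), and moving one
unit of mass between two entries preserves it. The solver random-restarts a
sum-preserving initial multiset and hill-climbs pairwise moves on
|Σ(kᵢ−k̄)² − target|. Exact SDs are often unattainable: with 12 values the
target squared-deviation sum for SD = 3 grid steps is 11·9 = 99, which is
odd, while any integer multiset with zero-sum deviations has an even
squared-deviation sum — the closest achievable SD is ≈ 2.98 steps. The
default tolerance is therefore ±0.5 px / ±0.5° (configurable, as is the
10,000-restart budget); within it every design spec realizes in
milliseconds. Sample SDs use the n−1 denominator throughout. Length and
orientation multisets are solved and shuffled independently before being
paired with layout cells, keeping the two features uncorrelated across
lines.

**Layouts.** Five counterbalanced experiment versions each carry one fixed
layout per task: 12 cells of a 5-column × 4-row grid with exactly 3 lines
per row, drawn by seeded sampling of 3 columns per row. The layout is
constant across all trials of a task, making line locations fully
predictable. Practice trials (10 per task) use the 5 main relevant means
with reduced SDs (4 px / 4.5°) and occupy all 12 cells of columns 1, 3, 5.

## The synthetic observer model

No observer model accompanies the experimental design itself, so the
package ships a minimal generative stand-in sufficient to exercise every
downstream stage:

- On each trial the observer's internal estimate of the ensemble mean is
  `true_mean + N(0, σ_task)`; the response is the probe nearest the
  estimate (exact midpoints resolve to the lower probe — a measure-zero
  tie, fixed for determinism).
- Per observer, (log σ_length, log σ_orientation) is bivariate normal with
  means (μ_L, μ_O), SDs (τ_L, τ_O) and correlation ρ_ability. The log-normal
  keeps noise positive; the single correlation is the latent "shared
  averaging ability" the analysis tries to recover.
- With probability `lapse_rate` a trial is answered uniformly at random;
  an `inattentive` observer answers every trial uniformly at random.

**Calibrated default preset** (`CohortParams()` /
`ensembles.observers.default_cohort`): n = 77, exp(μ_L) = 16.3 px,
exp(μ_O) = 15.0°, τ_L = 0.33, τ_O = 0.60, ρ_ability = 0.70,
lapse = 0.02, no inattentive observers. The location parameters come from
inverting the closed-form 5-AFC accuracy of a balanced design,
P(correct) = (8Φ(Δ/2σ) − 3)/5 with Δ the probe spacing, at the target
accuracies ≈ 0.43 (length) and 0.50 (orientation); the spreads and
ρ_ability were then calibrated once by simulation so that median marginal
accuracies, mean absolute errors (≈ 9.4 px / 9.3°) and the median
across-task MAE correlation (≈ 0.64, inside the design band [0.55, 0.75])
sit near the descriptives the cohort is meant to emulate. The preset is
frozen; it is a modelling choice, not a fitted quantity. A second preset
(`recruitment_cohort`: n = 102, 25% inattentive) emulates a raw sample
before screening.

**What the generator does not emulate:** sequential/learning effects,
reaction times, response biases (e.g. overweighting salient long lines),
eccentricity-weighted averaging, and any trial-level difficulty structure
beyond that induced by edge-vs-central probes. Passing recovery tests
therefore show that the pipeline recovers the latent structure *of this
model*, not that the model is a complete account of human averaging.

## Scoring and reliability

Per participant × task: accuracy, mean absolute error (the headline
measure), SD of *signed* errors (secondary, robust to constant response
bias), SD of absolute errors, and the trial count. A uniform random
responder's expected MAE on a balanced design is 1.6 probe spacings
(19.2 px / 21.6°) by enumeration of the 25 (true, response) pairs.

Cronbach's alpha is computed with the 120 per-trial absolute errors as
items: α = k/(k−1)·(1 − Σ item variances / variance of row sums). This is
the reliability that bounds the observable MAE correlation and enters the
attenuation correction.

## Screening

Trial easiness is the proportion correct per trial among participants above
chance (accuracy > 1/5) on that task, computed in a single pass (not
iterated). Person fit is the Pearson correlation of an observer's 0/1
correctness with the easiness vector, per task; a constant correctness
vector leaves it undefined, which is treated as failing. Inclusion: above
chance on both tasks, or fit ≥ 0.15 on every task at/below chance. A
manually supplied ID list covers exclusions with no algorithmic definition
(technical problems, misunderstood instructions).

**Operating characteristics.** The chance route is intrinsically leaky for
120-trial tasks: a uniform responder exceeds 20% accuracy on one task with
probability P(Bin(120, 0.2) > 24) ≈ 0.446, hence passes both tasks with
probability ≈ 0.20; the person-fit route admits a few percent more. The
achievable exclusion rate for fully random responders is therefore ≈ 77%,
with essentially all attentive observers retained. The test suite checks
the implementation against an independent Monte-Carlo oracle of the rule;
`scripts/acceptance.py` reports the measured rates.

## Bayesian correlation analysis

The Bayes factor uses the exact sampling density of the Pearson correlation
(hypergeometric form); only the ρ-dependent likelihood ratio is needed,
since r-only factors cancel:

log LR(ρ) = (n−1)/2·log(1−ρ²) − (2n−3)/2·log(1−ρr)
            + log ₂F₁(½, ½; (2n−1)/2; (1+ρr)/2) − log ₂F₁(½, ½; (2n−1)/2; ½).

The prior is beta(1/κ, 1/κ) stretched to (−1, 1); κ = 1 (uniform) is the
default and exposed as configuration. BF₊₀ integrates LR against the prior
truncated to (0, 1) by adaptive quadrature (relative tolerance 10⁻⁶) after
shifting by the log-integrand maximum, so Bayes factors of 10⁸ and far
beyond are computed without overflow. Three independent cross-checks guard
this integral in the tests: a Monte-Carlo average of LR over prior draws, a
published third-party implementation, and the exact symmetry
BF₊₀ = BF₁₀ at r = 0. A Fisher-z approximate path is provided for
comparison but never used for reporting, because its multiplicative error
grows in exactly the tail regime where decisive evidence lives.

Credible intervals are central quantiles of the normalized posterior under
the *two-sided* prior (the conventional report alongside a one-sided BF),
computed on a two-stage grid: a coarse scan locates where the log-posterior
is within 40 nats of its maximum, then a 20,001-point grid yields the CDF
by trapezoidal accumulation (endpoint error ≪ 10⁻³). At r = 0.65, n = 77
this gives (0.48, 0.75).

Jeffreys bands label BF: ≤1 favors-null, (1,3] very weak, (3,10]
substantial, (10,30] strong, (30,100] very strong, >100 decisive; bins are
half-open on the left so boundary values take the weaker label.

Disattenuation divides r by √(α₁α₂). The reported value is rounded to 2
decimals *before* squaring into the shared-variance proportion — matching
how such results are conventionally printed (0.69² = 47.6%) — with the
unrounded values carried alongside; |r| > 1 after correction is flagged,
never clamped.

The sequential design evaluates BF₊₀ at n = 75 pairs and after each added
observer (batch size configurable), stopping at the first crossing of 1/3
or 3. Under the calibrated preset the evidence at n = 75 is already far
beyond the upper boundary, so runs stop immediately with support for a
positive correlation.

## Pipeline and determinism

`run_full` spawns independent child seeds from the run seed
(`numpy.random.SeedSequence`), so design realization and cohort simulation
are decoupled but jointly reproducible: identical (seed, config) gives
byte-identical CSV/JSON outputs. A config hash is embedded in every output
file. Degenerate inputs (e.g. a zero-noise cohort with zero-variance
scores) propagate as flagged results — `r` null, reliabilities null —
rather than exceptions; infeasible configurations (e.g. an SD tolerance
below the lattice parity limit) fail with the stage name attached.

Problem sizes used by the shipped checks: 200 simulated cohorts for the
correlation-recovery summary, 40 for sequential stopping behaviour, 100
cohorts with 20% inattentive observers for screening rates, 3×10⁵
Monte-Carlo draws per point for the quadrature cross-check grid and 10⁶
draws for the single-point accuracy oracle.

## Known limitations

- The observer model is deliberately minimal (see above); its calibration
  targets first- and second-moment descriptives only.
- The five published spatial layouts are not recoverable; layouts here are
  constraint-equivalent seeded draws, which is immaterial to every
  downstream computation (positions never enter the observer model).
- The length-task reliability of simulated cohorts (α ≈ 0.87) runs a little
  below a real cohort's 0.93 at matched accuracy; raising it would require
  a wider ability spread than the matched MAE dispersion allows.
- Whether the original ensembles enforced SDs exactly or approximately is
  unknown; the tolerance is configurable and defaults to ±0.5 px / ±0.5°.
- Practice-trial relevant means are sampled uniformly from the 5 main
  values; the original assignment rule is not specified anywhere.
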