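# Methods

## The statistic

A session presents every unordered pair of `n_items` items exactly once
(n·(n−1)/2 trials; 190 for the default 20 items), in a random order. The
choices orient a complete directed graph; an unordered triple {i, j, k} is
*intransitive* iff its three edges form a directed 3-cycle, equivalently iff
no item of the triple wins both of its comparisons. A subject's score is
100 · (#cyclic triples) / (#fully observed triples).

Two facts anchor the scale. First, of the 8 equally likely orientation
patterns of one triple under independent fair-coin choices, exactly 2 are
cyclic, so the *expected* proportion under random choice is 25% — the
model's maximum over symmetric choice probabilities. Second, the *realized*
proportion of a single tournament is not capped at 25%: the attainable
maximum is (n³−n)/24 cyclic triples for odd n and (n³−4n)/24 for even n
(330/1140 ≈ 28.9% for n = 20). Tests assert the latter bound for single
subjects and the former only for expectations.

Scoring uses the tournament identity #cyclic = C(n,3) − Σᵢ C(dᵢ, 2) (dᵢ =
out-degrees) on hot paths; the triple-level table re-derives each triple
explicitly, and both paths are cross-checked against a brute-force triple
loop in the tests.

Triples with any missing constituent choice are excluded from numerator and
denominator, with the exclusion count reported (`n_excluded`). Position
features per triple: `last_trial_index` is the maximum of the three trial
indices (the trial that can close a cycle), `trial_index_variance` is the
sample variance (divisor 2) of the three indices; the divisor choice only
rescales regression coefficients and is recorded here.

## The random-utility noise model

Choice probability for A over B:

    p(A) = expit( ((1−α)·u_A + α·ε_A) − ((1−α)·u_B + α·ε_B) )

with ε drawn independently per option per trial (default standard normal;
logistic and uniform families available, parameterized by their SD). Choice
generation is deliberately two-stage — realize ε, compute p, then draw the
binary choice — so the logistic response contributes irreducible noise even
at α = 0. A `shared_epsilon` switch reproduces the degenerate variant in
which a single ε enters both terms and cancels, leaving α acting only as an
attenuation of the utilities; it exists for documentation and comparison,
not as the default.

At α = 1 the model reduces to independent fair coins regardless of the ε
family (any zero-mean symmetric ε preserves this), giving the exact 25%
anchor used by the acceptance checks.

**Reference configuration.** Utilities are evenly spaced on
[0, `REFERENCE_UTILITY_SCALE`] with scale 16 (logit units between the
extreme items), ε standard normal. The scale was fixed once, by simulation,
so that the α → intransitivity curve spans ~0.9% (α = 0) to 25% (α = 1)
with single-digit percentages — the regime clinical cohorts occupy — on its
steep, well-conditioned lower branch. Because the mid-curve depends
entirely on this (unobservable) utility/error configuration, an α estimate
is only meaningful relative to a stated configuration; every `SweepResult`
embeds its full configuration and config hash for that reason, and no
particular α value for a clinical group is asserted anywhere.

**Sweep and inversion.** `sweep_alpha` simulates `n_replicates` subjects
per grid point; sub-streams are keyed by (seed, α in fixed-point notation,
replicate index), so enlarging the grid or adding replicates never perturbs
existing cells. `invert_alpha` interpolates the isotonic (PAVA) fit of the
mean curve; the uncertainty interval inverts the mean ± SE curves.
Observations below the curve's minimum return the grid minimum flagged
`below_curve`; observations above its maximum raise, with the advice to
extend the grid or add replicates. Parameter recovery under the reference
configuration (cohorts of 31 subjects, true α ∈ [0.2, 0.4]) lands within
±0.05 in ≳97% of repetitions.

## Statistical stages

* **Group × task model.** log(pct + offset) regressed on orthogonal group
  contrasts (ETL−CON: (−1, +1, 0); MTL−mean(CON, ETL): (−½, −½, +1)), task
  centered (+½ preference, −½ number), their interactions, and a random
  intercept per subject (statsmodels `MixedLM`, REML; Wald-z p-values —
  the fitter's df convention is recorded in `ModelResult.description`).
  The focal term is `mtl_vs_controls:task`.
* **Log offset.** Default 1.0 percentage point. An offset near the
  statistic's resolution (half a triple ≈ 0.044pp) maps zero scores to
  log-values 3+ units below typical scores; the transform then *amplifies*
  the task-variance inequality it is meant to remove, and the group×task
  interaction drowns in control-task zero-inflation. With a 1pp offset the
  Bartlett statistic drops sharply pre → post transform (the transform's
  purpose), which is what the pipeline's own diagnostic (`bartlett.csv`)
  shows on generated cohorts. The half-triple policy remains available as
  `half_triplet_offset()` for sensitivity analyses; the offset used is
  always recorded in the model description.
* **Trial-level regressions.** Logistic models of `is_intransitive` on a
  z-scored position feature (`last_trial_index` or `trial_index_variance`),
  an MTL indicator and their interaction, with cluster-robust (by subject)
  standard errors. A mixed-logit alternative was considered; cluster-robust
  marginal models are less fragile at the low event rates involved, and the
  choice is recorded in each result's description. All-transitive input
  raises a separation error rather than returning a degenerate fit.
* **Response times.** (a) Logistic regression of intransitive-triple
  involvement on z-scored RT, RT², and group interactions (cluster-robust);
  a positive RT coefficient contradicts a speed-accuracy account of
  inconsistency. Constant RTs degenerate to a zero coefficient with a
  warning. (b) OLS of subject-mean RT on the group contrasts.
* **Item heterogeneity.** Randomized-block ANOVA of per-subject×item
  involvement counts (`counts ~ item + subject`), F-testing the item factor
  with df = (I−1), (I−1)(S−1). Subjects are blocks; ignoring them leaves
  subject-level variance in the denominator and miscalibrates the test.
  All-equal item means return F = 0 by definition.
* **Lesion stage.** LDI = |V_L − V_R| / (V_L + V_R): symmetric under side
  swap, 0 iff volumes are equal, < 1 for positive volumes; unit-free (only
  the ratio matters). Spearman rank correlation (midranks, two-tailed)
  against the preference-task intransitivity percentage; mismatched subject
  IDs raise with the orphan list. The left-vs-right predominance t-test is
  provided as a generic descriptive stage (`laterality_comparison`) —
  samples of the size this subset typically offers are underpowered, and it
  carries no calibration claims.
* Two-tailed α = 0.05 throughout; no multiple-testing correction (the
  number of fitted models is visible in the report output).

## The synthetic cohort generator

`generate_cohort` emulates the full study design: three groups
(default 30 CON / 30 ETL / 31 MTL), both tasks pair-complete per subject,
response times, and lesion records for a random subset of 16 MTL subjects.

* **Preference task.** Each subject draws a noise fraction α from a
  normal truncated to [0, 1] around the group center. Item utilities are
  the reference configuration with the *assignment* of utilities to item
  labels shuffled per subject (people differ in what they like; this also
  makes items exchangeable, matching a null item-heterogeneity test).
  On top, each item's utility carries a stationary mean-reverting AR(1)
  perturbation across trial slots (SD 1.2 utility units, autocorrelation
  time 60 trials): choices made far apart in the session see decorrelated
  values, which is the generative source of the positive trial-spacing
  effect, while the stationary variance keeps the baseline inflation
  bounded (and absorbed by calibration).
* **Number task.** The larger item code is objectively correct; responses
  flip with a per-subject lapse rate drawn from a Gamma distribution around
  the group rate (shape parameters 0.7 / 0.16 / 1.0 for CON / ETL / MTL —
  heavy-tailed for ETL, whose target regime combines a ~1% mean with a 0%
  median). Under i.i.d. lapses λ the per-triple cycle probability is
  exactly λ(1−λ) (enumerate the 8 flip patterns of an ordered triple), so
  group rates are inverted analytically from the target percentages:
  λ = (1 − √(1 − 4p))/2.
* **Consistency trait.** A Gaussian copula (r = 0.6) links each subject's
  α quantile and lapse quantile without changing either marginal: subjects
  who are noisy in one task tend to be noisy in the other. This is what
  gives the mixed model's random intercept real variance to absorb — a
  cohort with task-independent subjects would make the random-effect
  structure pointless.
* **Response times.** Lognormal (median 1.5 s, log-SD 0.4), +0.15
  log-units on trials involved in intransitive triples, +0.2 log-units for
  every MTL subject. Units and magnitudes are the generator's own
  convention; the analyses test signs, not scales.
* **Lesion link.** Expected LDI is a scaled logistic of the subject's true
  α (scale 0.8, steepness 6, midpoint 0.45 ≈ the MTL mean), plus Gaussian
  noise (SD 0.12), clipped to [0, 1); volumes are reconstructed from a
  total-volume draw and a random atrophied side, so `compute_ldi` recovers
  the generated index exactly. The link is a modelling convenience —
  synthetic by construction — tuned so the LDI-behavior Spearman ρ sits in
  the 0.6-0.8 band.
* **Calibration.** Group (α center, jitter SD) pairs were fixed once with
  `calibrate_alpha_params` (iterative moment matching under the full
  subject model): CON (0.240, 0.146), ETL (0.295, 0.169), MTL
  (0.442, 0.234), reproducing preference-task means ≈ 2.75 / 3.37 / 6.07%
  and SDs ≈ 1.4 / 2.2 / 5.1%. A single shared jitter cannot reproduce the
  3.5-fold spread between the CON and MTL SDs, which is why the jitter is
  per-group. The routine ships so users who change the utility scale,
  drift or error family can recalibrate.
* **Null cohorts.** `generate_null_cohort` equalizes all group parameters,
  removes the drift and the MTL RT shift, and keeps item shuffling — so
  group, spacing and item effects are all null by construction. Used for
  type-I calibration: at these settings the focal tests reject at ≈5%.

**What the generator does not emulate.** Real item-specific popularity
(utilities are exchangeable across items), learning or fatigue trends,
session-level RT autocorrelation, demographic or medication structure, and
any imaging detail beyond two volumes per subject. Passing tests therefore
demonstrate that the *pipeline* recovers effects of the modelled kinds at
study-like magnitudes — not that the clinical findings themselves are
reproduced; the fitted coefficients of the original patient data are not
recoverable from synthetic cohorts and are not targets.

## Numerical and design notes

* All randomness flows through `numpy` `SeedSequence`s keyed by explicit
  integer tuples (seed, group, subject / α, replicate); identical seeds give
  bitwise-identical outputs, and independent stages use disjoint key
  spaces.
* Problem sizes in the test suite (e.g. 200 null cohorts, 40 calibrated
  cohorts, 1000-replicate sweeps) were chosen as the smallest sizes at
  which the calibration bands and recovery rates are stable; the full suite
  runs in a few minutes on one core.
* `MixedLM` occasionally hits a singular information matrix when the
  random-intercept variance is near zero; the fitter falls back to Powell's
  gradient-free method in that case.
* Isotonic regression (for sweep inversion) uses `scipy`'s PAVA; flat
  segments of the fitted curve are collapsed before interpolation, so an
  observation on a flat stretch maps to its left edge.
* Item codes are 1-based; unordered pairs canonicalized as (min, max).
  Response times are seconds in memory; the reader accepts an `ms`
  declaration. Missing responses are accepted by the loader, flagged by
  `validate_design`, excluded triple-wise by the scorer, and counted.
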