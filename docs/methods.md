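# Methods

`walisar` re-implements the statistical machinery of an optogenetic
single-neuron-class valence screen as a tested, reusable pipeline.  Single
flies in narrow chambers choose between a dark half and an
optogenetically illuminated half; the package quantifies per-fly light
preference, turns per-genotype preference distributions into bootstrap
effect sizes, calls screen hits with an empirical-Bayes mixture model,
models how two co-activated receptor-neuron (ORN) channels combine, and
predicts odor valence from ORN firing rates through a supervised latent
projection.  A synthetic-data module supplies every input the analysis
consumes, so the whole pipeline runs and is tested without external data.

## Preference metric (TSALE / wTSALE)

For each analyzed 45-s lit phase, the first frame in which the fly's head
is in the lit half starts the test window.  Over the remainder of the
phase,

    TSALE = (t_light − t_dark) / (t_light + t_dark),

and the score is down-weighted by the fraction of the phase remaining
after the encounter: `wTSALE = TSALE × weight`, `weight =
post-encounter duration / phase duration`.  A fly that never finds the
light scores 0 with weight 0 and is retained, preserving sample sizes.
Frames are converted to durations on a regular grid (the last frame
inherits the median inter-frame spacing); the chamber midline belongs to
the lit half.

Two properties follow directly and are enforced by tests: `|wTSALE| ≤
weight ≤ 1`, and invariance (within one frame duration) to frame-rate
refinement of the same path.

One subtlety is intentional: conditioning on the first light encounter
gives the *raw* metric a small positive null bias for any walker with a
finite chamber-mixing time — a fly that begins a window deep in the lit
half contributes positive score until it mixes.  The bias is ~0.02 for
the default synthetic walker and cancels exactly in the test − control
difference (ΔwTSALE), which is the only quantity the analysis interprets.
Tests therefore bound the raw null mean (|mean| ≤ 0.05) and check ΔwTSALE
null calibration, rather than asserting a zero raw mean.

## Effect sizes

Valence is the mean difference `ΔwTSALE = mean(test) − mean(pooled
driver + responder controls)` with a 95% bootstrap CI
(bias-corrected-and-accelerated by default, percentile as a config
fallback; 5000 resamples by default).  Condition contrasts (ΔΔwTSALE) are
computed `within_fly` (same animals in both conditions: per-fly
differences first, then the group effect size) or `between_cohort`
(independent cohorts: difference of ΔwTSALE with independently
bootstrapped CIs).  Cohen's d (pooled-SD standardized mean difference) is
provided for cross-study comparisons.

## Empirical-Bayes screen

Each ORN's data is reduced to `D = M_exp − (M_ctrl1 + M_ctrl2)/2` with
standard error `S`, computed per light intensity and collapsed to
across-intensity medians (per-intensity fitting is an option).  The
moderated score is `Z = D / (α0 + S)` where `α0` is the 90th percentile
(linear interpolation) of all `S` — the standard "fudge factor" that
keeps small-variance ORNs from dominating.

Z scores are modeled as a mixture of a Gaussian null and a nonparametric
signal component split by sign, fitted by EM: the E-step assigns
membership probabilities; the M-step re-estimates the null's moments and
the signal's weighted kernel density; convergence is on the mixing
weights (tolerance 1e-6, max 500 iterations; non-convergence is flagged
in the fit report, never silent).  The signed posterior is
`sign(Z) × P(signal | Z)`; its complement is the local FDR.  Hits are the
largest posterior-threshold-consistent set whose *average* local FDR
stays below the threshold (default 0.25).

Semiparametric mixtures of this kind are degenerate without constraints —
the flexible component can swallow the null.  Four stabilizers are built
in (all configurable):

* **Zero assumption.**  Points within 1 null-SD of the null center
  contribute no support to the signal density.
* **Oversmoothed signal density.**  The signal KDE bandwidth is 3×
  Silverman's rule, so a handful of chance tail values cannot form a
  sharp signal mode.
* **Bounded null scale.**  The EM null SD is clipped to [0.9, 2.0]× a
  robust bulk scale (the max of MAD-, IQR- and central-60%-trimmed-SD
  estimators), blocking the null-shrink spiral.
* **Responsibility floor and leave-one-out evaluation.**  Points with
  signal responsibility below 0.2 contribute nothing to the signal
  density, and the KDE is always evaluated leave-one-out, so no
  observation vouches for its own signal membership.

An outlier filter (`|Z − median| > k·MAD`, default k = 20) excludes
corrupt values from the fit; removed items still receive posteriors by
evaluation under the fitted model.  The wide default is deliberate: the
moderated null is tight (MAD ≈ 0.25 Z-units on the synthetic screen), so
genuine hits sit at 15–20 MAD and a conventional k = 5 would remove the
biology the screen exists to find.

Calibration, measured by the test suite on the synthetic screen (46
ORNs, N = 52 test / 104 control): with no planted effects the screen
reports ≤1 hit in ≥90% of replicates; with 10 strongly valent ORNs
planted, recall ≥ 0.8 at realized FDR ≤ 0.25.

## Combination models

Three pooling rules predict a two-channel combination valence from the
single-channel valences: summation (`i0 + i1`), max-pooling and
min-pooling on absolute value with sign preserved.  On an exact
absolute-value tie the first argument wins (documented tie-break), so
max- and min-pooling jointly return both inputs otherwise.  Agreement
between observed and predicted combination valences is quantified by OLS
R² (paired-bootstrap CI) and Bland–Altman bias with limits of agreement
`bias ± 1.96 × SD(differences)`.

Channel weights are estimated by the bootstrap trio regression: each
replicate resamples the three score groups (channel 1, channel 2, combo)
with replacement at their own sizes, sorts each resample ascending,
pairs rank-wise into trios (truncating to the smallest group), and fits
`combo = β0 + β1·s1 + β2·s2` by least squares; 10,000 replicates by
default.  Groups are pre-sorted so the result is exactly invariant to
fly ordering; replicates with singular designs are dropped and counted.
The point (median β1, median β2) is summarized by its perpendicular
distance `|β1 − β2|/√2` from the summation diagonal, signed positive
when the first channel dominates.

**Known limitation.**  Rank pairing fits the relation between group
*quantile shapes*, and the quantile curves of two same-family score
distributions are affine in each other.  The individual β's are
therefore only weakly identified: the procedure pins down `β1 + β2` well
(and the bootstrap intervals cover the true pair), but point estimates
shrink toward an even split.  Tests assert exactly what the estimator
delivers — sum recovery, interval coverage, swap symmetry — not point
recovery of (β1, β2).

## Valence prediction

The odor panel (default scale 110 odors × 23 ORN classes) is explored
with Pearson correlation among ORNs and average-linkage clustering on
correlation distance, then reduced by PLS-DA — partial least squares
against one-hot class membership, classes being the valence sign —
with 8 latent variables by default (columns are centred and scaled
inside the fit).  Valence is regressed on the LV scores with a linear
model or SVR (linear, polynomial or RBF kernel); in-sample fit is
reported as adjusted R² `1 − (1 − R²)(n − 1)/(n − p − 1)` with p = number
of LVs.  Generalization error is the RMSE over ten shuffled 90/10 splits
in which the latent projection and the regressor are refit on each
training split — held-out odors never influence the projection (the test
suite verifies the absence of optimism with a pure-noise-target canary).
Odors can be re-weighted by `|Pearson r|` between their firing profile
and the per-ORN single-class valences; weighting applies in the
regression step (latent-step weighting is configurable out of scope).
Learning curves report train/validation RMSE over increasing training
sizes.

## Synthetic data

The generators define the study conditions the tests run under:

* **Trajectory level.**  The 12-step protocol (3 intensities × airflow
  off/on, each condition presented twice; 180-s steps of 30 s
  acclimatization / 45 s left lit / 30 s dark / 45 s right lit / 30 s
  dark; 25 Hz; 50-mm chamber) with cohorts of 52 test / 52 + 52 control
  flies.  Locomotion is a Gaussian-step random walk with reflecting
  walls; during lit phases the test genotype receives an additive drift
  toward the lit half proportional to the planted valence.  The step SD
  (3.5 mm/frame) is an *effective diffusion step* chosen so the walker
  mixes over the chamber on the ~5-s timescale of a running fly — it is
  not a literal per-frame displacement.  The drift constant
  (0.275 mm/frame per unit valence) is calibrated by Monte-Carlo so
  valence 1.0 yields mean wTSALE ≈ 0.5.  Only second-epoch presentations
  enter the analysis, matching the assay's validated protocol.
* **Score level.**  Truncated-normal wTSALE draws (null SD 0.25, matching
  the trajectory walker's score spread), with a configurable fraction of
  ORNs given a planted test-group shift (default magnitude 0.4, random
  sign) — the fast path for screen-scale testing.
* **Combination level.**  Trios share a standard-normal latent per fly
  (comonotone coupling, matching the estimator's rank pairing); the
  combination score follows the planted linear rule plus noise, truncated
  to [−1, 1].
* **Odor panel.**  Firing = baseline 100 + 30 × (latent factors ×
  loadings) + noise, spikes/s scale; valence is linear in the latent
  factors; class labels are the valence sign.

What the generators do **not** emulate: 2-D posture, wind-induced
locomotor change, habituation, inter-fly interaction, order effects, or
any feature fit to the real deposited data.  Passing tests therefore
demonstrate the statistical machinery's correctness and calibration
under the stated assumptions, not biological conclusions about real
flies.

## Reproducibility and problem sizes

Every stochastic routine takes an explicit seed; the pipeline derives
per-stage seeds by hashing (master seed, stage name), so adding a stage
never shifts another stage's stream, and the run manifest records the
config, derived seeds and SHA-256 checksums of all outputs.  Identical
seeds give byte-identical CSV/JSON outputs.

Test-suite problem sizes are chosen to exercise the study conditions at
desk scale: 100 replicate null screens and 50 replicate planted screens
at full screen size (46 ORNs × 156 flies × 3 intensities) via the
score-level generator; trajectory-level checks use batches of 200–1000
walkers and reduced cohorts (4–8 flies/role) for end-to-end runs; the
trio regression uses 1000 bootstrap replicates in tests (10,000 remains
the analysis default).

## Degenerate inputs and numerical choices

Zero-length or non-monotone frame sequences, empty score groups,
single-class panels, constant ORN columns and constant firing profiles
are rejected or flagged explicitly (never silently imputed).  Zero-
variance two-group comparisons collapse the bootstrap CI to a point.
Percentiles use linear interpolation throughout.  Singular bootstrap
designs are dropped and counted.  CV splits that lose a class are redrawn
a bounded number of times, then flagged.
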