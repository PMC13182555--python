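# Methods

This note documents the models, parameters and design choices behind
`socialtuning`: what the simulator and the synthetic cohort emulate, how the
tuning curves and their summary statistics are defined, and where the open
choices were and why they were resolved the way they were.

## Stimulus simulator

Animations show two (or, in the control, three) discs in an 800 x 600 px
world, 60 frames/s, with agent radius 12 px and fixed start positions at
(250, 300) and (550, 300). Detection clips last 6 s, discrimination clips
8 s. Coordinates use the screen convention (origin top-left, y downward).

**Chase (detection).** The predator pursues the prey; each pursuit step its
heading is the exact bearing to the prey rotated by a deviation angle drawn
uniformly from `[-s, +s]`, where the *subtlety* `s = 180 * (1 - directness)`
degrees. Directness 1 is a heat-seeking chase, directness 0 lets the
predator head anywhere. The deviation is redrawn every
`heading_resample_interval` frames and held in between — per-frame redraws
at 60 Hz would average to a nearly direct path and destroy the manipulation.
The prey flees straight away from the predator whenever it is within
`safety_distance`, and wanders otherwise (per-frame heading increment
uniform in `+-wander_max_turn`, constant `wander_speed`).

**Invisible chase (control).** The prey starts at a uniformly random
on-screen position and is invisible; the predator genuinely chases it. A
visible mimic starts at the second regular start position and applies the
negation of the hidden prey's realized per-frame displacement, so the two
*visible* agents show correlated motion without genuine pursuit. All stored
positions are quantized to a 2^-22 px binary grid; on that grid the
mimic/prey displacement anti-symmetry is an exact identity in double
arithmetic on every frame where neither agent was wall-clamped (quantization
perturbs any per-frame displacement by less than 5e-7 px, far below every
stated tolerance).

**Charge (discrimination).** Both agents wander for a random period
(uniform over `[charge_wander_min, charge_wander_max]` = [60, 180] frames),
then a randomly chosen initiator charges straight at the other at exactly
`charge_speed` px/frame; the other responds after `charge_response_delay` =
12 frames. Contact (distance <= 24 px) returns both to wandering and
schedules the next cycle. Charging agents move toward a point inside the
convex legal region, so charge steps are never wall-clamped and the
per-frame displacement during a charge equals the level's charge speed to
within the quantization error. The wander-period range was chosen so an 8 s
clip contains several approach-retreat cycles and the slowest level
(1.5 px/frame) still reaches contact.

**Kinematics defaults and calibration.** The attribute values used to
generate the original stimuli are not public. The free defaults
(`predator_speed` 2.0, `prey_speed` 3.0, `wander_speed` 2.5,
`wander_max_turn` 8 deg/frame, `safety_distance` 100 px,
`heading_resample_interval` 60 frames) were calibrated once against the
published macro-statistic of the detection stimulus set — the Pearson
correlation of chase directness with mean inter-agent distance, reported as
r = -0.69 — and then frozen. Under these defaults a default 84-animation
set yields r between -0.79 and -0.65 across 20 disjoint seed sets, with
per-level mean distances decreasing monotonically in directness. A
slower-than-prey predator keeps the chase unresolved over 6 s, so pursuit
geometry rather than capture drives the distance statistics.

Boundary handling clamps positions to the legal box and reflects the
heading component normal to the wall; agents never leave the screen and
never teleport. All simulators are deterministic given the animation seed:
identical specs produce bitwise-identical trajectory CSVs.

## Trial designs

Detection sessions have 7 directness levels spaced evenly on [0, 1] with 12
trials each (84 trials); discrimination sessions have 7 charge speeds
evenly spaced on [1.5, 9] px/frame with 10 trials each (70 trials); the
mixed session interleaves 42 trials of each task in six 14-trial blocks
(block order 121212 or 212121, drawn per participant); the control session
fully crosses chase and invisible-chase conditions with the levels (a
6-level variant that drops directness 0 is available). Predator color and
starting side are balanced within task to within one trial. Trial order is
a full seeded shuffle without run-length constraints — the simplest
defensible randomization. The rating-scale label side is drawn once per
participant and stored as metadata only; ratings are always coded on the
canonical 0-1 axis.

## Synthetic cohort

Each synthetic observer owns a ground-truth detection sigmoid
`S(x) = gamma + (1 - gamma - lam) / (1 + exp(-beta (x - alpha)))` and a
discrimination line `L(x) = c + m x` on the normalized attribute axis,
plus a response model. Population parameters are drawn from truncated
normals; the defaults describe a mildly heterogeneous adult cohort:

| parameter | mean | sd | bounds | note |
|---|---|---|---|---|
| gamma, lam | 0.12 | 0.12 | [0, 0.45] | shifts from the scale extremes |
| alpha | 0.50 | 0.12 | [0.05, 0.95] | sigmoid center |
| beta | 12 | 4 | [2, 30] | sigmoid slope |
| c | 0.15 | 0.08 | [0, 0.5] | line intercept |
| m | 0.65 | 0.15 | [0.05, 1.0] | line slope |
| rating_noise_sd | 0.08 | 0.02 | [0.02, 0.2] | trial-level rating noise |
| lapse_rate | 0.02 | 0.01 | [0, 0.2] | uniform-rating lapses |
| miss_rate | 0.02 | 0.01 | [0, 0.2] | timed-out trials |
| id_alpha | 0.30 | 0.10 | [0, 0.8] | identification threshold |
| id_beta | 8 | 2 | [1, 20] | identification slope |
| session2_jitter_sd | 0.03 | 0 | — | between-session drift |

The asymptote spread (sd 0.12) was chosen so the implied between-subject
distribution of the bias statistic spans roughly 0.2-0.8, matching the
width of published per-participant histograms of that statistic.

A trial's rating is `clip(truth(x) + Normal(0, noise_sd), 0, 1)`; with the
lapse probability the rating is replaced by Uniform(0, 1), and with the
miss probability it is missing (responses are dropped, not imputed, before
level means). Detection trials add a 2AFC predator-identification outcome
drawn from `Bernoulli(0.5 + 0.5 * logistic(id_beta (x - id_alpha)))`, which
is exactly chance at directness 0 in the saturated-threshold limit and
rises toward 1 with directness — an observer forced to guess when there is
no chase. Session 2 perturbs each true parameter with small Gaussian jitter
(sd 0.03), emulating small but real session-to-session drift.

Traits: 14 dimensions (five AQ subscales, two PANAS affect scores, five
NEO-FFI factors, loneliness, and number of close friends) are generated as
weighted sums of the z-scored true curve summaries (the bias-PSE composite
and range, per task) plus unit-variance noise; the friend count is a
monotone exponential transform of its latent score, floored to an integer.
A zero linkage matrix yields a null cohort.

What the generator does *not* emulate: reaction times, learning or drift
within a session, serial dependence between trials, questionnaire
item-level structure, or participant inattention beyond uniform lapses.
Passing recovery tests therefore demonstrate that the analysis machinery is
correct and well-calibrated under this response model — not that real
human data satisfy it.

## Tuning curves and derived parameters

Level means (missing trials dropped) are fit per participant/session/task:
the sigmoid by bounded least squares (`gamma, lam` in [0, 1], `alpha` in
[-0.5, 1.5], `beta` in (0, 100]) and the line by closed-form OLS. The
sigmoid uses a fixed 3 x 3 x 3 x 3 multi-start grid; all 81 starts are
advanced together by a batched damped Gauss-Newton with box projection and
the best basins are polished by scipy's bounded trust-region solver; ties
in RSS are broken toward the smallest slope. On a fixed noisy test dataset
the resulting RSS beats every point of a 20^4 brute-force parameter grid.
All-equal level means leave the center and slope unidentifiable; the fit
degenerates to the flat curve `gamma = y_bar, lam = 1 - y_bar` with a flag.

Derived parameters: `lb`/`ub` (shifts from the scale extremes; `lb = c`
and `ub = 1 - c - m` for the line), `bias = lb / (lb + ub)`,
`range = 1 - lb - ub` (the slope `m` for the line), the objective midpoint
`PSE` (where the curve crosses rating 0.5; closed form
`alpha + (1/beta) logit((0.5 - gamma)/(1 - gamma - lam))` for the sigmoid,
`(0.5 - c)/m` for the line), the subjective midpoint `alpha`, and
`sigma = 1/beta`. Clamping rules: a curve entirely above the midline
(`lb > 0.5, ub < 0.5`) has no crossing in [0, 1] and its PSE is set to 0; a
nominal crossing beyond the attribute range (`lb < 0.5, ub > 0.5`) sets it
to 1; a negative range flags the participant for exclusion; `lb + ub = 0`
leaves bias at its neutral 0.5 with a degeneracy flag. By construction
`lb + ub + range = 1` for both families.

**AIC family comparison.** Both families are compared by Gaussian AIC
`n ln(RSS/n) + 2k`, with k counting the curve parameters plus the error
variance (5 vs 3). The substrate matters: on the 7 level means the richer
sigmoid family (which nests near-linear shapes at small `beta`) wins on a
truly linear observer about 20% of the time regardless of the noise level —
an intrinsic property of comparing k=5 against k=3 on seven points. The
default therefore evaluates the AIC on the raw trial residuals (curves are
still *fit* to level means): with 70-84 trials per session the comparison
labels ~90% of truly linear observers linear and essentially all
steep-sigmoid observers sigmoid, in line with the decisive preference rates
such data show in practice. The level-means substrate remains available via
`fit_both(..., aic_on="means")`. A preference is called *decisive* when the
AIC difference exceeds 5.

## Reliability

`nrmse` divides the root-mean-square error of a curve's predictions on the
7 level means by the rating-scale width (1.0 by default; observed-range
normalization is available). The within/across comparison transfers each
participant's other-session parameters onto the target session's level
means and compares, by paired t-test, against a leave-one-out baseline that
averages the *parameter values* of all other participants' target-session
fits (averaging predictions instead is available behind a flag; parameters
were chosen as the more literal reading of a group-average curve).
Participants excluded in either session are dropped pairwise per analysis.

ICC(2,1) — two-way random effects, absolute agreement, single measure — is
computed from the ANOVA mean squares
`(MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))` with k = 2 sessions;
it penalizes constant session offsets that a Pearson correlation would
ignore, and is undefined (NaN) when both variance components vanish.
Session-shift tests are per-parameter paired t-tests with 95% CIs.

## Group-level models

The rating model is a linear mixed-effects regression
`rating ~ level + mean_dist + trial_number` with crossed random intercepts
for participant and stimulus, estimated by REML via variance components on
a single grouping level. Covariates are rescaled to comparable [0, 1]
ranges (attribute to its normalized axis, mean distance by the world
diagonal, trial number by session length) so coefficients are readable on
the rating scale. Model AICs (from the fitted likelihood) support the
with/without-mean-distance comparison. The identification-accuracy model
uses the same predictors with a logistic link; since no frequentist
crossed-random-effects logistic estimator exists in the stack, it is fit as
a fixed-effects logistic regression with participant-clustered robust
standard errors, which leaves the population-level slope estimate
consistent. Singular fits and separation are reported as flags, never
crashes.

## Associations

Cross-task structure uses Pearson correlations among the robust parameters
(detection bias/range/PSE x discrimination bias/PSE) with Benjamini-
Hochberg FDR over the six cross-task cells. The bias-PSE composite z-scores
both measures across participants and subtracts PSE_z from bias_z (the two
live on different axes — ratings vs attribute — so z-scoring precedes the
difference). Trait regressions enter all 14 z-scored traits simultaneously
in OLS; predictors are z-scored to make coefficients comparable across
heterogeneous questionnaire scales, and the friend count enters as-is after
z-scoring (no log transform). Inference: percentile bootstrap over
participants (rank-deficient resamples redrawn and counted) for
per-coefficient 95% CIs, and a permutation test that shuffles the outcome
10,000 times and counts permuted models whose R^2 strictly exceeds the
observed one (no add-one smoothing; the p-value can legitimately be 0 at
finite repetitions).

## Numerical and scaling choices

Problem sizes in the test and acceptance suites were chosen at desk scale:
parameter-recovery and family-preference checks use 200-observer cohorts,
the reliability comparison 100 observers over two sessions, null
calibrations 150-500 simulated cohorts with reduced permutation/bootstrap
repetitions (99-300), and the stimulus-set statistic 84 animations per seed
set over 20 seed sets. These sizes put all Monte-Carlo standard errors well
inside the asserted margins. All randomness flows from explicit seeds;
stage-level child seeds are derived as `seed XOR crc32(stage)` so changing
one stage leaves the others' outputs unchanged.

## Known limitations

* The simulator is a behavioral emulation, not a re-implementation of the
  original stimulus engine; only its published macro-statistics were
  matched.
* The wander model is a simple bounded random walk; real stimulus engines
  use steering behaviors with inertia.
* The accuracy model has no 0.5 guessing floor, so its marginal prediction
  can slightly undershoot observed accuracy at directness 0.
* Trait generation is linear-Gaussian; real questionnaire scores are
  bounded, discrete and skewed.
* The exclusion pipeline exposes only curve-shape flags (negative range,
  unfittable levels) and missingness; attention-based exclusions used with
  human data are out of scope.
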