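# Methods

This note documents the models, algorithms and numerical choices behind
`infobias`, in the spirit of a statistical package's model documentation: it
states what is computed and under which assumptions, not empirical claims
beyond what the test suite itself verifies.

## Task schedules

A session is three 80-trial blocks. Each outcome (win, loss) has its own
probability trajectory for appearing under shape A; the realised sides are
independent Bernoulli draws per trial, so knowing where the win is says
nothing about the loss. Stable trajectories are constant at 0.50. Volatile
trajectories alternate between 0.15 and 0.85 in runs of 14–30 trials and are
constructed to average exactly 50% over the block: run lengths are drawn
uniformly from [14, 30] until the block is filled, then the final two runs
(one at each level) are adjusted so both levels occupy exactly 40 trials,
rejecting and resampling when the adjustment leaves [14, 30]. Treating the
50% average as a hard constraint has a combinatorial consequence: a balanced
80-trial block always has exactly four runs with r1+r3 = r2+r4 = 40, so
realised run lengths actually span [14, 26] — three runs would require a
40-trial run, and five runs cannot split 40 trials into three runs of at
least 14. The starting level is a fair coin per stream. Trials are 1-based
everywhere. All stochastic operations take an explicit seed; a master seed
fans out to per-block (and per-participant) streams via `SeedSequence.spawn`,
which keeps cohorts byte-reproducible.

For block sizes other than 80 the same algorithm applies; exact balance is
infeasible for odd lengths or lengths below two minimum runs, and these are
rejected with an error rather than approximated.

## Behavioural models

All five variants share the conventions: beliefs in force on trial i reflect
outcomes up to trial i−1; the task is full-information (both outcome
locations are revealed regardless of choice), so beliefs update on every
trial; probability estimates start at 0.5 and the value learner starts at 0.

* **m1 (primary)** — independent Rescorla–Wagner trackers per valence,
  r ← r + α(out − r), with choice probability σ(β_win·r_win − β_loss·r_loss).
  Free parameters: α_win, α_loss ∈ (0,1), β_win, β_loss ≥ 0.
* **m2 (model-free)** — one value v_A updated from the joint outcome
  win−loss ∈ {−1, 0, 1} with a single learning rate. Because both outcome
  locations are observed each trial, v_B = −v_A exactly, and the softmax
  acts on β(v_A − v_B) = 2βv_A. (Whether β multiplies v_A or the difference
  is a pure reparameterisation absorbed by the β grid.)
* **m3 (Bayesian learner)** — a parameter-free hierarchical filter per
  valence (below), with two inverse temperatures entering only at the choice
  stage.
* **m4** — m1 with a single shared temperature.
* **m5** — m4 with a risk warp r̃ = 2^(−(−log₂ r)^γ) applied to both
  estimates before the softmax; γ = 1 is the identity (implemented exactly,
  avoiding a log/exp round-trip, so m5 at γ = 1 reproduces m4 bitwise).

A floor of 1e-12 is applied to choice probabilities before logs so that no
parameter combination yields −∞ log-likelihood.

A caution for property testing: relabelling the shapes (A↔B) maps
P(choose A) to 1 − P(choose A) only when the two temperatures are equal — in
the valence-specific softmax the relabelled logit picks up a constant
β_win − β_loss — and, for m5, only at γ = 1, since the risk warp is not
symmetric about 0.5.

## The hierarchical volatility filter (m3)

The generative model assumed by the learner: the outcome probability r
drifts between trials through a beta kernel with mean r and concentration
exp(−v); the log-volatility v performs a Gaussian random walk with variance
exp(k); k is static. Inference is exact on a fixed grid — 50 points for r on
[0.01, 0.99], 30 for v on [−8, 2], 15 for k on [−4, 2] (the k range is this
package's choice; the construction leaves it open) — with a uniform joint
prior, alternating Bernoulli updates and kernel propagation. The per-trial
output is the predictive posterior mean of r, i.e. the estimate a learner
would act on before seeing that trial's outcome. A diagnostic warns when
more than half the predictive mass for r sits on the two edge grid points.
With a small concentration (high volatility) the mean-parameterised beta
kernel is U-shaped; this matches the task's 15%/85% contingencies and is
intended.

## Grid-posterior estimation

Parameters are estimated per participant and per block. The posterior over
the parameter grid is proportional to the prior (uniform by default) times
the Bernoulli choice likelihood, computed in log space and normalised by
log-sum-exp; point estimates are the expectations of the marginal
posteriors. Default grids: learning rates, 50 equally spaced points on
[0.01, 0.99]; inverse temperatures, 40 log-spaced points on [0.1, 30]; γ, 20
log-spaced points on [0.2, 5]. A reduced option (30 learning-rate and 20
temperature points) exists for large model-comparison batteries; a
refinement test verifies that doubling the resolution moves expected
parameters by less than 0.02 on representative data.

Choices from the first 10 trials of each block are excluded from the
likelihood, matching the pupil-analysis exclusion; belief updating still
runs from trial 1, because the exclusion concerns the use of choice data,
not learning.

BIC per block is k·ln(n) − 2·lnL with n = 70 likelihood-contributing trials
and the log-likelihood evaluated at the posterior-expected parameters (the
reported estimates), then summed over the three blocks. Using the
expected-parameter likelihood rather than the grid maximum is a deliberate
choice, made for consistency with the reported estimates.

The likelihood grids exploit the model structure: r_win trajectories depend
only on α_win and r_loss only on α_loss, so belief series are computed once
per learning-rate value and broadcast over the temperature axes. The large
m1/m4/m5 grids use compiled (numba) kernels with the exponentials hoisted
out of the pairwise loop; a pure-numpy implementation of the identical
floored likelihood is kept and cross-checked in the tests (agreement to
1e-10).

Group analyses transform parameters to the real line: the logit for
learning rates and the natural log for temperatures (and γ). Boundary values
are clamped at 1e-6 with a warning.

## Synthetic cohorts

The generator defines the study conditions: cohorts default to the m1
sampler with learning rates uniform on (0.05, 0.6) and temperatures uniform
on (2, 10); block order is counterbalanced (half the cohort, rounding down,
per order); earnings follow the ±15-pence rule (+15 if the chosen shape
carries the win only, −15 if the loss only, 0 if both or neither).

Pupil traces emulate a 500 Hz pupil-area recording: baseline level 5 (a.u.)
+ slow sinusoidal drift (amplitude 0.5, period 90 s, random phase) +
Gaussian noise (sd 0.15) + one gamma-shaped dilation per trial (shape 3,
scale 0.5 s → peak 1 s after outcome onset, 6 s support, matching the
analysed window) + blinks as dropout intervals (Poisson rate 0.08 Hz,
durations 0.1–0.4 s). Trials span 9 s with outcome onset at 1.5 s, leaving
a full 1 s baseline and 6 s post-outcome window inside each trial. Win and
loss dilations share the trial's single outcome-onset event (the
simultaneous-presentation reading; a sequential-onsets variant would need
separate markers and is left as an extension). The per-valence amplitude is
base ± difference/2 for obtained/unobtained outcomes, with the difference
set per valence and block volatility; defaults (base difference 0.25/0.45,
volatility gain 0.15/0.45 for win/loss) emulate a larger loss response and a
larger loss-volatility effect. What the generator does **not** emulate —
gaze-position artifacts, luminance responses, saccade foreshortening,
non-stationary blink clustering — bounds what passing tests show: the
preprocessing chain recovers injected effects from data with this noise
structure, not from every real recording.

## Pupillometry preprocessing

The chain is order-exact: linear interpolation across invalid samples
(edges filled with the nearest valid value, every filled sample flagged) →
zero-phase low-pass Butterworth, order 3, 3.75 Hz cut-off, applied
forward-backward (the order is this package's choice, validated by
frequency-response bounds: ≥95% amplitude retained at 0.5 Hz, ≤10% at
10 Hz) → session-wide z-transform with the population (n) denominator →
per-trial epochs of 6 s post-outcome minus the mean of the 1 s pre-outcome
baseline, one epoch per valence sharing the trial's onset → exclusions:
epochs with strictly more than 50% of the post-outcome window interpolated,
and trials 1–10 of each block; a participant is dropped when more than 99%
of their epochs are excluded → per block × valence, the mean obtained-epoch
minus mean unobtained-epoch difference vector, averaged within six 1 s bins,
with the overall 6 s mean kept for between-subject correlations. Cells with
no included epoch on either side are reported missing rather than imputed.

## Group statistics

The mixed repeated-measures ANOVA implements the classical balanced-design
sums-of-squares decomposition with subjects nested in the between factor
(block order): every within effect, and its interaction with the between
factor, is tested against the corresponding effect × subject-within-group
mean square; the between effect is tested against subjects-within-groups.
Balance is required and checked (unbalanced cells raise an error naming the
offender). Sums of squares are computed by inclusion–exclusion over cell
means, which for balanced data reproduces the textbook partition exactly
(the test suite verifies SS additivity at 1e-8, agreement with an
independent per-subject contrast oracle on 2×2 designs, and agreement with
`pingouin.mixed_anova` on one-within designs). No sphericity correction is
applied to 2-level factors (none is needed); a Greenhouse–Geisser epsilon is
available for the 6-level time-bin factor but off by default. Follow-up
tests are uncorrected paired contrasts on the transformed parameters, with
the multiplicity procedure left as a configuration choice.

The "outcome volatility" recoding attaches volatility to each valence's own
schedule role (win rows are "volatile" in the win-volatile block, loss rows
in the loss-volatile block), enabling the asymmetry test of whether the
volatility effect differs by valence.

Change scores difference each valence's logit-transformed learning rate
between its volatile and stable block (so scores may exceed ±1), paired with
the matching difference of the 6 s mean pupil response. Correlations are
Pearson with df = n − 2 (a rank-based option exists via the recovery tests'
Spearman checks); two independent correlations are compared with Fisher's
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)). Degrees of freedom are
always computed from the actual complete-case n of each analysis, not
hard-coded, so behavioural (n) and pupil (n − excluded) analyses can differ.

## Problem sizes and numerical tolerances

The recovery batteries use cohorts of 20 agents × 240 trials (parameter
recovery on the default grids; model comparison across all five variants on
the reduced grids) and 10 cohorts of 6 participants for pupil-effect
recovery; the type-I error check runs 1000 null cohorts of 16 participants.
These sizes give stable pass/fail behaviour at the tested thresholds while
keeping the full suite to a few minutes. Hand-value checks are at 1e-12;
posterior normalisation at 1e-10; ANOVA oracle agreement at 1e-8. The
compiled and reference likelihood paths agree to 1e-10, and the γ = 1 /
tied-temperature model equivalences are exact.

## Known limitations

* The Bayesian learner's transition kernels follow one concrete reading of
  the hierarchical construction (beta drift parameterised by mean and
  log-volatility concentration, Gaussian drift of v, static k); other
  discretisations of the same idea would differ in detail, though the
  qualitative behaviour (higher estimated volatility for 15/85 streams,
  faster tracking) is verified by tests.
* The ANOVA handles balanced designs only; unbalanced cohorts must be
  reduced to complete cases first (the group-analysis driver does this for
  the pupil battery).
* The pupil generator is phenomenological, not biophysical; recovery
  results transfer to real data only to the extent that blinks, drift and
  noise dominate real artifact structure.
* Stable blocks (p = 0.50) carry little information about learning rates;
  per-block estimates there lean on the grid prior, which inflates
  posterior-expected learning rates toward the grid centre. Averaging over
  blocks or analysing the volatile blocks mitigates this, and it is the
  main reason parameter recovery is tighter for within-cohort rank order
  than for absolute values.
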