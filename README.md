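# infobias

Valence-specific volatility learning: a complete, reusable analysis pipeline
for a two-outcome probabilistic learning task in which the volatility of win
and loss outcomes is manipulated independently.

## The scientific problem

Affective bias — weighting negative events more (or less) heavily than
positive ones — can be framed as a rational response to how *informative*
each class of event is. When an outcome's stimulus association is volatile
(changeable), each occurrence carries more information about future trials,
and a normative learner should raise its learning rate for that outcome
specifically. Testing this requires a task where win and loss contingencies
vary independently, behavioural models that estimate separate learning rates
per valence, and physiological measures (pupil-linked arousal, a proxy for
central norepinephrine activity) that may track outcome-specific volatility.

This package implements all of it:

* **Task schedules** (`infobias.schedule`) — three 80-trial blocks. A
  volatile outcome alternates between p = 0.15 and p = 0.85 of appearing
  under shape A in runs of 14–30 trials, balanced so the block mean is
  exactly 50%; a stable outcome stays at p = 0.50. Block 1 has both outcomes
  volatile; blocks 2–3 have exactly one volatile each, counterbalanced.
* **Behavioural models** (`infobias.models`) — five variants usable
  generatively and for likelihood evaluation. The primary model tracks
  r_win(i) and r_loss(i), the estimated probabilities that the win/loss sit
  under shape A, by Rescorla–Wagner updates

      r(i+1) = r(i) + α · (out(i) − r(i)),       r(1) = 0.5

  with valence-specific learning rates α_win, α_loss, mapped to choice by a
  softmax P(choose A) = σ(β_win·r_win − β_loss·r_loss). Comparators: a
  model-free value learner (one α, one β), a parameter-free hierarchical
  Bayesian volatility learner (grid filter over probability, volatility and
  volatility drift), a single-temperature variant, and a risk-warped variant
  r̃ = 2^(−(−log₂ r)^γ).
* **Fitting** (`infobias.fitting`, `infobias.model`) — per-participant,
  per-block full grid posteriors with uniform priors; point estimates are
  marginal posterior expectations; the first 10 choices per block are
  excluded from the likelihood (beliefs still update through them). Models
  are compared by BIC = k·ln(n) − 2·lnL summed over the three blocks.
* **Synthetic cohorts** (`infobias.agents`) — simulated agents with known
  parameters plus raw 500 Hz pupil traces with blinks, noise, drift, and
  outcome-locked dilations whose obtained-vs-unobtained amplitude difference
  is injectable per valence × block volatility.
* **Pupillometry** (`infobias.pupil`) — blink interpolation → zero-phase
  3.75 Hz low-pass Butterworth → session z-transform → outcome-locked epochs
  (1 s baseline, 6 s post-outcome) → exclusions (>50% interpolated, first 10
  trials) → obtained-minus-unobtained difference timeseries in 1 s bins.
* **Group statistics** (`infobias.stats`) — balanced mixed repeated-measures
  ANOVAs (block volatility × valence × [time bin] within, block order
  between), logit/log parameter transforms, change-score correlations and
  Fisher r-to-z comparison of correlations.

## Worked example

Simulate one participant whose win learning rate (0.45) far exceeds their
loss learning rate (0.10), then re-estimate both from the choices alone:

```python
import infobias as ib
from infobias.models import ModelParams

schedule = ib.generate_session("win_volatile_first", seed=7)
truth = ModelParams(alpha_win=0.45, alpha_loss=0.10, beta_win=6.0, beta_loss=6.0)
session = ib.simulate_agent("m1", truth, schedule, seed=11)

model = ib.ValenceLearningModel(session.trials, variant="m1")
res = model.fit()
print(res.summary())
```

```
Valence-specific learning model fit
============================================================
Variant: m1   free parameters/block: 4
Trials/block in likelihood: [70, 70, 70]
Log-likelihood (total): -75.973
BIC (summed over blocks): 202.928
------------------------------------------------------------
 block    alpha_win  alpha_loss    beta_win   beta_loss
     1       0.6038      0.3012      2.3852      1.6620
  (sd)       0.1966      0.2506      1.2987      1.1910
     2       0.4481      0.0755     15.7680     16.9507
  (sd)       0.0806      0.0482      5.7039      5.9911
     3       0.5921      0.1441      5.1153      5.1086
  (sd)       0.2060      0.0813      2.4426      2.4758
============================================================
```

The posterior-expected learning rates recover the injected asymmetry
(α_win ≫ α_loss in every block; rows marked `(sd)` are posterior standard
deviations). `res.transformed_params()` returns the logit/log-transformed
values used by the group ANOVAs, and `res.bic` feeds
`infobias.compare_models` for cohort-level model comparison.

A command-line interface mirrors the library:

```bash
infobias schedule generate --order winfirst --seed 3 --out schedule.csv
infobias simulate behaviour --model m1 --n 20 --seed 5 --out-dir cohort/
infobias fit --model m1 --trials cohort/participant_001.csv --out fit.csv
infobias pupil preprocess --trace trace.csv --markers markers.csv --out out/
infobias analyze --behaviour behaviour.csv --out analysis/
```

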