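# Methods

## The task model

A hidden target sits at a horizontal position `x` on a screen whose width
defines the coordinate unit (percent screen width, psw; range 0–100).  On
each trial `x` is drawn from one of two Gaussian location priors — narrow
(μ = 35, σ = 1.0 psw) or wide (μ = 70, σ = 2.5 psw) — identified to the
responder by target color.  The sensory cue is a cloud of n = 8 dots whose
horizontal positions are i.i.d. Gaussian draws about `x` with a
condition-specific SD σ_l ∈ {0.6, 3, 6} psw (low / medium / high noise).
The cloud is rescaled about its sample mean so the displayed SD equals σ_l
exactly on every trial; the sample mean itself (the centroid, the ideal
observer's sufficient statistic) is preserved by the rescaling.  Responses
are scored by an interval-overlap rule: the 1-psw-wide response bar
catches the target when it overlaps the 0.5-psw feedback dot by at least
half the dot, equivalent to |response − target| ≤ 0.5 psw.

The narrow prior's SD appears in the source material both as 1.0 psw (the
design parameter) and 1.3 psw (the value quoted next to empirical probe
SDs).  The package defaults to 1.0 and exposes `narrow_sigma` in the
config; the two are not silently reconciled, and the formula-oracle
validation covers σ_p ∈ {1.0, 1.3, 2.5}.

### Schedules

Sessions have five blocks of 300 main trials.  In the staged design
(exp1/exp2) blocks 1–3 contain the four low/medium pairings at 75 trials
each and the high-noise cue enters only in blocks 4–5 (six pairings × 50);
in the full design (exp3) all six pairings appear at 50 trials per block.
exp2 is schedule-identical to exp1 — the instruction manipulation it
stands for is an observer property, not a schedule property.  Main trials
are organised into runs of 20 (10 per prior); within each run every
prior's targets are affinely moment-corrected
(x′ = μ_p + (x − x̄)·σ_p/sd(x)) so that an ideal learner accumulating one
run of feedback recovers the prior's mean and SD exactly.  One dot-free
prior-only probe is inserted after every 9 main trials with alternating
prior identity, giving 166 probes (83 per prior) over 1500 main trials.
Probes do not count toward the 300 main trials per block (the source
counts are only mutually consistent under this reading).

SD convention: "SD equal to the true SD" does not specify the divisor; the
package uses the population (divide-by-n) form by default for both the
dot-cloud rescaling and run-target correction, with `sd_mode: sample`
available (the choice rescales dot spread by √(8/7)).  Coordinates are
continuous; an optional `pixel_grid` flag rounds dot positions to an
n-pixel raster.

## Observer models

All simulated observers respond

    response = w·(centroid + ε_li) + (1 − w)·μ̂_p + ε_m,

with internal centroiding noise ε_li ~ N(0, σ_li²) (per likelihood
condition), motor noise ε_m ~ N(0, σ_m²), and μ̂_p the running
feedback-derived estimate of the prior mean (Welford mean/SD per prior;
initialised at screen centre, SD 10 psw, until feedback arrives).  The
strategies differ only in the weight w:

- **ideal_bayes** — w = (n/σ_l²)/(n/σ_l² + 1/σ_p²) with true parameters.
- **bayes_transfer** — the same form, but with the learned prior SD and
  the cue SD read off the displayed cloud; a new noise level is therefore
  down-weighted immediately, with no feedback about it.
- **internal_noise** — w = σ̂_p²/(σ_li² + σ̂_p²): the observer discounts
  the cue only by its own centroiding variability and ignores the
  external dot scatter.
- **lookup_table** — a per-(prior, likelihood) weight learned by a
  variance-normalised delta rule (below); a never-seen pairing borrows
  the weight of the experienced condition with the nearest σ_l, which is
  exactly what produces "no transfer".
- **fixed_weight** — a constant w (scalar or per condition); the
  workhorse for parameter recovery.

On prior-only probes the observer responds by sampling its believed prior
(plus motor noise), so probe response SD tracks the *learned* prior SD —
the regime in which probe statistics are informative about prior
learning.  A mean-responding variant (`prior_only_sampling=False`) is
available; under it probe SD reflects only motor noise.

### The rote learner's update

The delta rule on the squared error gives Δw ∝ −e·(c − μ̂) with
e = response − target.  In raw psw units the gradient scale is the
condition variance (σ_l²/n + σ_li² + σ̂_p², roughly 1–13 psw²), so a raw
step size is unstable for some conditions and glacial for others.  The
update is therefore normalised by a per-condition running estimate of
(c − μ̂)² (initialised from the observable cloud variance/n plus the
believed prior variance), making `learn_rate` a per-trial fractional
step toward the error-minimising weight.  The default is 0.0005 per
trial (time constant ≈ 2000 trials), set from a design constraint rather
than data: the defining property of a rote learner in a transfer test is
that a borrowed mapping persists through the first block of a new
condition (~50 trials per pairing), so the expected within-block drift
must stay below the weight-estimation noise of a per-cell regression
(≈ 0.03 at 50 trials).  The cost of that constraint is slow convergence:
the rote observer is still far from the error-minimising weights at
session end, which is consistent with treating it as a qualitative
alternative hypothesis rather than a fitted model.  Per-subject rates
are drawn log-normally (log-SD 0.5) around the default.

### Expected catch rate

For a constant-weight responder the error about the target is Gaussian
with variance w²σ_l²/n + (1−w)²σ_p² + σ_m², so the catch probability is
2Φ(0.5/σ_err) − 1.  It is maximised at the ideal weight when σ_m does not
depend on w, which is how the cost of a suboptimal weight in expected
reward is quantified.

## Synthetic cohorts

Cohorts stand in for behavioral data that were never deposited.  Each
subject gets a fresh schedule, observer and parameter draw (all spawned
from one seed; every draw is logged in the subject table).  Per-subject
σ_li are log-normal around condition medians 0.6 / 1.0 / 1.5 psw (low /
medium / high; log-SD 0.3) — increasing with dot scatter, and sized so
that control-task response variability exceeds the true centroid
variability in the low and medium conditions, as the control data show.
Motor noise is log-normal around 0.5 psw (log-SD 0.25).  Default cohort
sizes are 26 (exp1) and 12 (exp2/exp3).  The control task scatters
targets uniformly over [20, 80] psw (no learnable prior; placement is a
package default, not a documented value) and responses are
centroid + ε_li + ε_m, so SD(centroid − response) estimates the combined
internal variability — the estimator necessarily conflates centroiding
and motor noise, and the package keeps σ_li and σ_m separate in
simulation while estimating their combination, as any prior-free control
design must.

What the generator does **not** emulate: learning-to-criterion, fatigue,
lapses (a lapse-rate hook exists, default 0), sequential/criterion-
switching strategies, reaction times, and the verbal-instruction
manipulation (representable only as different observer parameters).
Passing tests therefore certify the pipeline's correctness on data whose
generative model is known, not any claim about human behavior.

## Analysis chain

1. **Outlier exclusion** — per (prior, likelihood) pairing, pooled over
   blocks and subjects, trials with |error| strictly above the 99th
   percentile (linear-interpolation definition) are dropped; strictness
   means an all-equal pairing drops nothing.  Per-pairing and per-subject
   drop counts are reported.
2. **Weight regression** — OLS of response on centroid per
   (subject, prior, likelihood, block) cell (a pooled grain is
   available); the slope is the weight on the cue.  Cells under 10 trials
   or with a degenerate regressor are flagged, not fitted; slopes outside
   [−0.2, 1.2] are fitted but flagged.
3. **Cue-statistic comparison** — pooled R² of responses against mean,
   iteratively-trimmed robust average (drop dots > 2 sample SDs from the
   running mean until stable; untrimmed clouds reduce to the mean),
   median and mid-range.
4. **Prior-only summary** — per-subject probe bias and SD; across
   subjects, mean bias with a one-sample t-test and the median subject SD
   next to the true σ_p.
5. **Internal-noise estimation** — SD(centroid − response) per subject
   (per likelihood condition or pooled; both modes provided since the
   source is silent on the grain).
6. **Model predictions and MSE** — per subject × condition weights for
   the external (ideal), internal-noise and overall-variability models;
   MSE against final-block fitted weights, models ranked ascending.
7. **Transfer contrast** — per-subject weight(medium) − weight(high) in
   the first block containing the high-noise cue (immediate gap) and the
   change in weight(high) to the next block (exposure slope), each with a
   seeded 10⁴-resample percentile bootstrap CI over subjects.  Inference
   throughout is t-tests plus bootstrap; repeated-measures ANOVA
   machinery is deliberately out of scope.

## Numerical choices and validation scales

- The grid-posterior oracle evaluates the Gaussian prior × Gaussian cue
  posterior on a 40001-point grid spanning ±12 combined SDs and takes the
  posterior-mean slope between two displaced cue values; it agrees with
  the closed forms to ~1e-14, far inside the 1e-6 validation tolerance.
- Moment corrections and dot-cloud rescaling are exact up to float
  round-off (~1e-14 observed; asserted at 1e-9).
- Degenerate draws (zero sample SD) are redrawn; sub-2-target run
  remainders place targets at the prior mean; a short final run is
  moment-corrected at its own size.
- Validation problem sizes: cohorts of 12 subjects, full 1666-trial
  sessions, 100 control trials per condition, 10⁵-trial Monte-Carlo for
  the catch rate, 10⁴ bootstrap resamples — sizes at which every check's
  sampling error is well below its decision margin.
- The strategy-discrimination check tests a point null (the rote
  cohort's immediate gap ≈ 0) with a stochastic CI; the rote learner's
  small residual within-block drift plus a mild selection effect of the
  1% exclusion rule on high-noise cells leaves a bias of ≈ +0.01, so the
  95% CI covers zero for most but not every seed (~90% across seeds
  checked).  This mirrors the marginal character of the corresponding
  empirical null result.

## Known limitations

- Observer heterogeneity is limited to noise and learning-rate draws;
  real cohorts also vary in strategy and biases within strategy.
- The bayes_transfer observer reads the cue SD off the displayed cloud,
  which the exact-SD rescaling makes noiseless; with rescaling disabled
  its weights would fluctuate trial to trial.
- The internal-noise strategy uses the learned prior SD, so its early
  trials deviate from the closed-form prediction until the belief
  converges; model comparison uses final-block weights for this reason.
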