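# cuecatch

Simulation and analysis of Bayesian cue combination in a one-dimensional
target-localization ("catch the hidden target") psychophysics task.

## The problem

An observer must localize a hidden target on a horizontal axis.  Two
sources of information are available: a **prior** — the target's location
is drawn from one of two Gaussian distributions (narrow: μ = 35, σ = 1 in
percent screen width; wide: μ = 70, σ = 2.5), learnable from trial-by-trial
feedback — and a **likelihood** — a cloud of 8 dots scattered about the
target with SD σ_l ∈ {0.6, 3, 6} psw, rescaled so the displayed scatter is
exact on every trial.  An ideal Bayesian observer reports a precision-
weighted blend of the cloud centroid c and the prior mean,

    response = w·c + (1 − w)·μ_p,      w = (n/σ_l²) / (n/σ_l² + 1/σ_p²),

so the regression slope of responses on centroids measures the weight
placed on the sensory cue.  The interesting questions are whether a
learner *transfers* its learned priors to a cue-noise level it has never
seen (immediately down-weighting it, as Bayes requires) or instead
behaves like a rote look-up table, and whether deviations from the ideal
weights are better explained by the observer's *internal* centroiding
noise σ_li (w = σ_p²/(σ_li² + σ_p²)) or by the *overall* cue variability
(σ_lo² = σ_l²/n + σ_li²).

Because the corresponding behavioral data are not publicly deposited,
this package pairs the full experimental design (trial scheduler with
exactly moment-matched runs, dot-cloud stimulus generator, catch/score
rule) with simulated observer cohorts, and runs the complete analysis
chain on the resulting trial logs: outlier exclusion, weight regression,
cue-statistic R² comparison, prior-only probe summaries, internal-noise
estimation from a control task, three-model MSE comparison, and
bootstrap transfer contrasts.  It is aimed at computational-psychophysics
researchers who want a tested reference implementation of this design for
power analysis, parameter-recovery studies, or as a template for their
own variants.

## Worked example

Simulate a 12-subject cohort whose members weight the cue by their own
internal noise, plus their prior-free control sessions, then analyze:

```python
import cuecatch as cc
from cuecatch.cohort import CohortParams, generate_control_cohort

log, subjects = cc.generate_cohort("exp1", 12, CohortParams(strategy="internal_noise"), seed=7)
control = generate_control_cohort(subjects, 100, seed=8)
res = cc.analyze_log(log, control, seed=0)

print(res["model_mse"][["model", "mse", "n_cells"]].to_string(index=False))
print("best cue statistic:", res["best_estimator"],
      {k: round(v, 4) for k, v in res["estimator_r2"].items()})
print(res["prior_only"][["prior_id", "median_response_sd", "true_sigma_p"]].to_string(index=False))
```

prints

```
   model      mse  n_cells
internal 0.010328       72
external 0.039011       72
 overall 0.044043       72
best cue statistic: mean {'mean': 0.9964, 'robust_average': 0.9957, 'median': 0.995, 'midrange': 0.9939}
prior_id  median_response_sd  true_sigma_p
  narrow            1.127915           1.0
    wide            2.483510           2.5
```

The model-comparison table shows the analysis correctly assigning the
lowest MSE to the internal-noise account when that is the ground truth;
the R² ranking (mean > robust average > median > mid-range) reproduces
the expected ordering for a mean-taking responder; and the prior-only
probe SDs track the learned prior SDs (1.13 vs 1.0 narrow, 2.48 vs 2.5
wide), showing that the simulated learners acquired both prior means and
variances from feedback.

The same pipeline is scriptable from the shell:

```sh
cuecatch simulate run.yaml --out-dir out        # trial logs + manifest
cuecatch analyze out/exp1_cohort.csv --control out/exp1_control.csv --out-dir results
cuecatch report results/summary.json            # markdown tables
```

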