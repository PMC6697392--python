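# uvalley

Psychophysics and ROI-statistics toolkit for the **uncanny valley** (UV):
the observation that people like artificial agents more the more humanlike
they appear — until the agents become *too* humanlike, at which point
likability drops sharply. `uvalley` quantifies that drop from rating data,
models accept/reject choices between agents, composes regional neural
valuation patterns from linear–nonlinear humanlikeness signals, and
provides the event-related ROI time-course machinery used to test such
models. A synthetic-data generator with known ground truth drives
validation, parameter recovery and error-rate calibration throughout.

Intended users: cognitive/decision neuroscientists and psychophysicists who
want a tested, scriptable implementation of the UV analysis chain, either
for simulation studies or for their own behavioral tables.

## The model in brief

**UV depth (rating task).** For a subject's per-stimulus mean ratings, fit
likability on humanlikeness by OLS over all stimuli *except* the UV-relevant
category (artificial humans), extrapolate to that category's mean
humanlikeness *h̄*, and take

&nbsp;&nbsp;&nbsp;&nbsp;UV depth = (β₀ + β₁·h̄) − observed mean likability,

so positive depth means the category is less liked than the linear
humanlikeness continuum predicts. A leave-one-category-out residual profile
and a cubic fit of the full likability–humanlikeness cloud provide
converging quantifications. Group inference is random effects: per-subject
depths into one-sample *t* tests.

**Decision variable (choice task).** Choices y ∈ {0 = first, 1 = second}
between sequentially presented agents follow a multiple logistic regression
on relative attributes Δ = first − second:

&nbsp;&nbsp;&nbsp;&nbsp;y ~ logistic(β₀ + β₁·Δlikability + β₂·Δfamiliarity + β₃·Δhumanlikeness),

and the subject's decision variable is DV = β₁Δlik + β₂Δfam + β₃Δhum (no
constant). Equally populated DV bins with a two-parameter logit give the
psychometric curve; the mean |DV| per category contrast, regressed on the
contrast's humanlikeness gap, gives a *choice* UV depth.

**Linear–nonlinear region models.** TPJ carries a linear humanlikeness
signal a + b·h; FFG an inverse linear signal d − e·h selectively for
nonhuman agents with a constant response c to humans; DMPFC a
human-detection step; and VMPFC the multiplicative combination
m + k·TPJ·FFG, whose product of rising and falling terms yields a selective
trough at the most humanlike nonhuman category — the neural UV.

**ROI statistics.** DCT high-pass (128 s cutoff), z-normalisation, ×10
windowed-sinc oversampling, epoching to trials × time; per-timepoint OLS
across trials without orthogonalisation (VIFs reported); AIC-gated
inclusion of the human-detection regressor; leave-one-subject-out (LOSO)
effect extraction to avoid selection circularity; Pearson + robust (Huber)
across-subject associations at Bonferroni-adjusted alphas; and a
convolution-domain PPI.

## Worked example

```python
import uvalley as uv

params = uv.SubjectParams()              # ground truth: uv_dip = 0.8
data = uv.design.simulate_subject(params, seed=3)

means = uv.stimulus_means(data["ratings"])
res = uv.uv_depth(means)
print(f"UV depth: {res.uv_depth:.3f} (slope {res.slope:.3f})")

dsg = uv.choice_design_frame(data["choice_trials"], means)
model = uv.fit_choice_logistic(dsg)
print(f"accuracy: {model.accuracy:.3f}  pseudo-R2: {model.pseudo_r2:.3f}")
print("betas:", model.betas.round(2))
```

prints

```
UV depth: 0.652 (slope 0.616)
accuracy: 0.806  pseudo-R2: 0.449
betas: [ 0.5  -1.66 -0.39 -0.27]
```

The estimated depth of 0.65 recovers this subject's injected dip of 0.8 up
to rating noise (across populations the estimator is unbiased; see below).
The negative likability/familiarity/humanlikeness weights mean the subject
systematically chooses the agent they rated more likable, more familiar and
more humanlike — under the Δ = first − second convention a preference for
the *first* stimulus pushes y toward 0.

A population-level run, ready-made designs and CSV/JSON reports are
available from the command line:

```bash
uvalley simulate --seed 1 --out sim/
uvalley uv --ratings sim/ratings.csv
uvalley choices --choices sim/choices.csv --ratings sim/ratings.csv
```

## Layout

| module | contents |
|---|---|
| `uvalley.design` | stimulus/trial types, task design builders, population config, all simulators, CSV/JSON persistence |
| `uvalley.uvquant` | UV depth, leave-one-category-out residuals, cubic fit, group tests |
| `uvalley.choicemodel` | relative attributes, logistic decision model, DV, psychometric curve, choice UV depth |
| `uvalley.lnl` | linear–nonlinear region models, fitting, multiplicative VMPFC reconstruction |
| `uvalley.roistats` | HRF, preprocessing, per-timepoint GLM, AIC selection, LOSO, associations, PPI |
| `uvalley.recovery` | ground-truth recovery and calibration studies |

See `docs/methods.md` for the generative model, parameter defaults and
numerical choices.
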