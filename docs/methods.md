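# Methods

This note documents the generative model behind the synthetic-data
module, the estimators, the defaults and the numerical choices, and what
the validation studies do and do not establish.

## Task design

Six stimulus categories span a humanlikeness continuum — mechanoid robots,
humanoid robots, androids, artificial humans, humans with physical
impairments, humans without — with six exemplars each (36 stimuli). The
artificial-human category is the UV-relevant one: maximally humanlike
among the nonhuman agents. Each stimulus is rated twice on continuous 1–5
analog scales for likability, familiarity and humanlikeness (72 rating
trials, seeded permutation order). The choice task forms nine category
contrasts: unimpaired humans against every other category (five
contrasts) and androids against every remaining category except
unimpaired humans (four). Each contrast holds 12 trials over unique
exemplar pairs, six starting with each category (108 trials total).
Event timing uses a fixed 8 s stimulus slot plus an inter-trial interval
drawn uniformly from 2–6 s; BOLD is sampled at TR = 2 s.

## Generative model and defaults

Each subject s is a parameter vector drawn from population Gaussians
(between-subject SDs in parentheses), clipped to admissible ranges where a
sign constraint exists. Ratings for a stimulus with latent category
humanlikeness *h*:

* humanlikeness = h + ε,  ε ~ N(0, σ²),  σ = 0.4 (0.05)
* likability = α + β·h − d·1[artificial human] + ε,
  α = 1.0 (0.1), β = 0.6 (0.06), dip d = 0.8 (0.3); d = 0 is the null
* familiarity = 3.0 + w·(likability signal, centered) + ε, coupling
  w = 0.62 (0.05)

All three are clipped to [1, 5]. Latent humanlikeness values are
(1.6, 2.2, 2.9, 3.2, 4.1, 4.5). Two deliberate placements: the scale
midrange keeps clipping negligible at σ = 0.4 (the nearest boundary is
≈1.9σ away), and the artificial-human latent (3.2) sits near the centroid
of the other categories' latents, so the errors-in-variables attenuation
of the likability-on-humanlikeness fit — stimulus-mean humanlikeness over
two presentations has reliability ≈0.93 — produces a depth bias well below
0.01 rating units. With a less central target the same attenuation would
bias depth by several hundredths and distort null calibration. The
familiarity coupling w is calibrated so the within-subject
likability–familiarity shared variance averages R² ≈ 0.39, the regime the
analysis is meant to operate in (familiarity is informative but not a
clone of likability).

Choices: P(second chosen) = logistic(β₀ + β₁Δlik + β₂Δfam + β₃Δhum) with
Δ = first − second computed from the subject's *empirical* per-stimulus
rating means — what a real analysis would possess. Default betas
(0, −1.3, −0.55, −0.6) with SDs (0.15, 0.24, 0.14, 0.17): negative
because a subject who prefers the more likable agent chooses the *first*
stimulus (y = 0) when Δlik > 0. These defaults place the refitted model at
≈86% classification accuracy and McFadden pseudo-R² ≈ 0.52, i.e. choices
are predictable from ratings but far from deterministic. Confidence is
1 + 1.2·|DV| + N(0, 0.4), clipped to [1, 5] — the monotone-in-|DV| link is
a modeling choice; nothing downstream depends on its exact form.

Region amplitudes per rating trial follow the linear–nonlinear models
driven by latent humanlikeness, plus N(0, 0.2²) trial noise
(response ranges span roughly 1–7 units, a favorable SNR regime — see
Limitations). Defaults: TPJ (a, b) = (1.5, 0.5); FFG (d, e, c) =
(3.6, 1.0, 1.6); DMPFC baseline 1.0, human step 1.5, nonhuman slope 0
(the step-only model is the default; the graded nonhuman slope is an
option); VMPFC (k, m) = (1.0, 1.6). The amygdala carries a negative-gain
code (gain 0.8) of the centered likability signal, with no confidence
component. A population parameter `neural_coupling_corr` (default 0.5)
correlates a subject's behavioral dip with their VMPFC gain so behavioral
and neural UV depths covary across subjects, enabling across-subject
association studies with known ground truth.

The VMPFC composition includes both gain and offset because amplitudes
are unit-free; a bare product would only be identified up to an affine
map. With e > 0 the product of the rising TPJ and falling FFG terms is a
concave quadratic over the nonhuman range, which is what places the
trough on the most humanlike nonhuman category.

## Estimators

* **UV depth** fits per-stimulus subject-mean ratings (30 non-target
  points by default) rather than category means, for statistical
  efficiency; an option adds androids to the target set. The per-subject
  significance test uses per-presentation deviations (12 observations:
  6 exemplars × 2 repetitions), with the prediction evaluated at each
  stimulus's mean rated humanlikeness.
* **Leave-one-category-out residuals**: category c's residual comes only
  from the fit excluding c. Note an asymmetry that is easy to miss: with
  a pure artificial-human dip, the artificial residual equals −d exactly,
  but the *other* categories' fits still contain the dipped data, so
  their residuals are small yet nonzero.
* **Logistic fits** use maximum likelihood (statsmodels Logit). Complete
  or quasi-complete separation is caught (convergence failure or
  implausible coefficient magnitude) and refit with a small L2 penalty
  (α = 0.1, intercept unpenalised), flagged and warned. McFadden
  pseudo-R² is used; CIs are Wald. The DV excludes β₀ by default.
* **Psychometric curve**: quantile bins (counts differ by ≤1), logit
  fitted on trial-level data by default; a bin-level binomial GLM is the
  alternative. Default 8 bins.
* **Degenerate inputs**: zero x-variance raises a singular-fit error;
  constant outcomes report R² = 0 with a degenerate flag; zero-variance
  t tests and correlations return flagged NaN results rather than
  failing.
* **Preprocessing**: DCT-basis projection implements the 128 s high-pass
  (the basis convention of the SPM ecosystem); filtering precedes
  z-normalisation; sinc oversampling uses a Blackman-windowed kernel with
  32-sample half-width and reflective padding — its interpolation error
  on band-limited signals is below 10⁻⁴, and the half-width samples at
  each session edge are treated as approximate.
* **Per-timepoint GLM**: regressors are mean-centered and compete without
  orthogonalisation; standardized coefficients by default; VIFs are
  computed once on the trial-level design and exact collinearity is
  refused naming the offending regressor.
* **AIC model selection** sums the per-timepoint Gaussian AIC
  (2k + n·log(RSS/n)) over the analysis window (default 2–8 s
  post-onset, configurable and reported); the human-detection extension
  is accepted only if total AIC improves *and* the candidate's group
  effect is significant.
* **LOSO extraction**: each subject's locus is chosen from the other
  subjects' mean map; n subjects → n refits. The in-sample "naive"
  extractor is included purely to demonstrate the selection bias LOSO
  removes.
* **Associations**: two-sided Pearson plus Huber-IRLS robust regression;
  alpha 0.0125 in rating-UV contexts, 0.0167 in choice-UV contexts, 0.05
  otherwise. All tests in the package are two-sided.
* **PPI** operates in the convolution domain: the trial-level
  psychological contrast is expanded to event amplitudes, convolved with
  the HRF and multiplied with the seed series. Deconvolution is
  deliberately omitted: on simulated data the neural series is known, and
  an exact-neural-series mode (`convolve_psych=False`) is provided for
  that case. A constant psychological vector is refused as collinear.
* **HRF**: double gamma on the gamma-density parameterisation — peak
  delay 6 s, undershoot delay 16 s, unit dispersions, undershoot ratio
  1/6, peak normalised to 1; recorded in the HRF object and overridable.
  The dominant component's analytic mode (delay − dispersion = 5 s) pins
  the peak-time oracle.

## Validation studies and their scope

`uvalley.recovery` packages the studies run by the test suite and the
reproduction script, at these reference sizes: 500 populations × 21
subjects for UV-depth recovery (grand-mean depth within ±0.05 of the
generating 0.8); 1000 null replicates for type-I calibration of the group
test and the association (5% ± 2 points); 500 subjects for per-coefficient
95%-CI coverage of the choice betas (≥90%); 5000 trials for psychometric
slope recovery; 500 replicates for LNL reconstruction (r ≥ 0.7) and
valley-location checks; 500 replicates for BOLD-chain unbiasedness, where
each noisy run is compared against the identical pipeline applied to its
noise-free series (rescaled by the normalisation ratio), an exact
conditional reference. These sizes keep the whole suite under a minute
per study on one core while leaving Monte-Carlo error far inside each
tolerance.

What passing does **not** show: the generator draws Gaussian rating noise
with a single SD for all three scales, knows the true HRF, has stationary
white BOLD noise plus a deterministic drift, and contains no motion,
physiological artifacts, scanner drift nonstationarity, session effects,
response biases or rating-scale granularity. Recovery under these
conditions validates the *estimators* — their algebra, calibration and
freedom from selection bias — not robustness to real-data pathologies.
In particular the LNL trial noise (SD 0.2 against response ranges of
several units) is a favorable SNR; real single-trial ROI amplitudes are
substantially noisier, and parameter-recovery precision would degrade
accordingly.

## Known limitations

* Ratings are generated and analysed as continuous; visual-analog
  granularity and anchoring effects are not modeled.
* The familiarity model is a one-parameter coupling to the likability
  signal; real familiarity has category structure of its own.
* The choice UV depth extrapolates from four contrasts — a fit this small
  is deliberately faithful to the task's structure but statistically
  fragile in single subjects.
* PPI omits deconvolution (see above); with empirical BOLD this is an
  approximation whose quality degrades at short TRs and fast designs.
* The per-subject UV significance test treats presentations as the
  observation unit; stimuli would be the conservative alternative
  (12 vs 6 observations), and a sensitivity analysis can swap them by
  aggregating the deviations.
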