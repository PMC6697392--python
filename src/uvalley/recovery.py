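"""Ground-truth recovery and calibration studies.

Because the generator knows its own parameters, every analysis operation
can be validated end-to-end: inject a known uncanny-valley dip, known
choice weights or known region parameters, run the corresponding
estimator, and measure bias, coverage or error-rate calibration.  These
studies back the package's test suite and the reproduction script; they
are ordinary library code so users can rerun them at other settings.

All studies are deterministic given their seed (seeds are spawned from a
single :class:`numpy.random.SeedSequence`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from . import choicemodel, design, lnl, roistats, uvquant
from .uvquant import _ols_line

__all__ = [
    "design_counts", "uv_recovery_study", "null_rejection_study",
    "association_type1_study", "rating_correlation_study",
    "choice_recovery_study", "psychometric_slope_study",
    "lnl_recovery_study", "signal_chain_study", "loso_null_study",
    "oracle_checks", "default_population_summary",
]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# shared fast paths over the default design
# ---------------------------------------------------------------------------

class _RatingDesign:
    """Per-trial arrays of the default rating design, built once."""

    def __init__(self, repetitions: int = 2):
        stimuli = design.build_stimulus_set()
        trials = design.build_rating_trials(stimuli, repetitions, seed=0)
        self.stimuli = stimuli
        self.trials = trials
        ids = [s.id for s in stimuli]
        index = {sid: i for i, sid in enumerate(ids)}
        self.stim_ids = ids
        self.stim_idx = np.array([index[t.stimulus.id] for t in trials])
        self.latent = np.array([t.stimulus.category.latent_humanlikeness
                                for t in trials])
        self.artificial = np.array([t.stimulus.category.name == "artificial_human"
                                    for t in trials])
        self.n_stimuli = len(ids)
        self.stim_category = np.array([s.category.name for s in stimuli])
        self.stim_target = self.stim_category == "artificial_human"
        self.counts = np.bincount(self.stim_idx, minlength=self.n_stimuli)

    def stimulus_mean(self, values: np.ndarray) -> np.ndarray:
        return np.bincount(self.stim_idx, values, minlength=self.n_stimuli) / self.counts


def _subject_depth(dsn: _RatingDesign, params, seed: int,
                   with_residuals: bool = False):
    h, l, _ = design.simulate_rating_values(params, dsn.latent, dsn.artificial, seed)
    mh = dsn.stimulus_mean(h)
    ml = dsn.stimulus_mean(l)
    res = uvquant.uv_depth_arrays(mh, ml, dsn.stim_target)
    if not with_residuals:
        return res.uv_depth, None
    cats = list(dict.fromkeys(dsn.stim_category))
    profile = np.empty(len(cats))
    for i, c in enumerate(cats):
        m = dsn.stim_category == c
        slope, intercept = _ols_line(mh[~m], ml[~m])
        profile[i] = np.mean(ml[m] - (intercept + slope * mh[m]))
    return res.uv_depth, (cats, profile)


# ---------------------------------------------------------------------------
# design combinatorics
# ---------------------------------------------------------------------------

def design_counts() -> dict:
    """Trial/contrast counts of the default design."""
    stimuli = design.build_stimulus_set()
    rating = design.build_rating_trials(stimuli, 2, seed=0)
    contrasts, choices = design.build_choice_design(stimuli, 12, seed=0)
    per_contrast = pd.Series([t.contrast.label for t in choices]).value_counts()
    first_ref = pd.Series(
        [t.contrast.label for t in choices
         if t.first.category.name == t.contrast.reference_category.name]
    ).value_counts()
    return {
        "n_stimuli": len(stimuli),
        "n_rating_trials": len(rating),
        "n_choice_trials": len(choices),
        "n_contrasts": len(contrasts),
        "trials_per_contrast": int(per_contrast.iloc[0]),
        "trials_per_contrast_uniform": bool(per_contrast.nunique() == 1),
        "reference_first_per_contrast": int(first_ref.iloc[0]),
        "order_balanced": bool(first_ref.nunique() == 1
                               and first_ref.iloc[0] * 2 == per_contrast.iloc[0]),
    }


# ---------------------------------------------------------------------------
# UV depth recovery and type-I control
# ---------------------------------------------------------------------------

def uv_recovery_study(n_populations: int = 500, seed: int = 0,
                      config: design.PopulationConfig | None = None) -> dict:
    """Recover the injected population UV dip from simulated ratings.

    For each replicate population (21 subjects by default) the per-subject
    UV depth and leave-one-category-out residual profile are estimated;
    reports the grand-mean estimated depth against the generating dip mean
    and how often the artificial-human residual is the most negative entry
    of the population-mean profile.
    """
    cfg = config or design.PopulationConfig()
    dsn = _RatingDesign(cfg.repetitions)
    s_pop, s_sub = _spawn_seeds(seed, 2)
    rng = np.random.default_rng(s_sub)
    means, most_neg = [], 0
    for rep in range(n_populations):
        pop = design.sample_population(cfg, seed=s_pop + rep)
        depths, profiles = [], []
        for p in pop:
            d, (cats, prof) = _subject_depth(
                dsn, p, int(rng.integers(2 ** 31)), with_residuals=True)
            depths.append(d)
            profiles.append(prof)
        means.append(np.mean(depths))
        mean_prof = np.mean(profiles, axis=0)
        most_neg += cats[int(np.argmin(mean_prof))] == "artificial_human"
    return {
        "generating_dip": cfg.means["uv_dip"],
        "mean_estimated_depth": float(np.mean(means)),
        "bias": float(np.mean(means) - cfg.means["uv_dip"]),
        "sd_of_population_means": float(np.std(means, ddof=1)),
        "residual_most_negative_rate": most_neg / n_populations,
        "n_populations": n_populations,
    }


def null_rejection_study(n_replicates: int = 1000, seed: int = 0,
                         alpha: float = 0.05) -> dict:
    """Type-I error of the group UV test under a dip-free population."""
    cfg = design.PopulationConfig().null()
    dsn = _RatingDesign(cfg.repetitions)
    s_pop, s_sub = _spawn_seeds(seed, 2)
    rng = np.random.default_rng(s_sub)
    rejections = 0
    for rep in range(n_replicates):
        pop = design.sample_population(cfg, seed=s_pop + rep)
        depths = [_subject_depth(dsn, p, int(rng.integers(2 ** 31)))[0]
                  for p in pop]
        rejections += stats.ttest_1samp(depths, 0.0).pvalue < alpha
    return {"rejection_rate": rejections / n_replicates, "alpha": alpha,
            "n_replicates": n_replicates}


def association_type1_study(n_replicates: int = 1000, n_subjects: int = 21,
                            seed: int = 0, context: str = "default") -> dict:
    """Type-I error of the across-subject Pearson association test."""
    alpha = roistats.ALPHA_BY_CONTEXT[context]
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        b = rng.standard_normal(n_subjects)
        n = rng.standard_normal(n_subjects)
        rejections += stats.pearsonr(b, n).pvalue < alpha
    return {"rejection_rate": rejections / n_replicates, "alpha": alpha,
            "n_replicates": n_replicates}


def rating_correlation_study(n_subjects: int = 200, seed: int = 0) -> dict:
    """Population likability-familiarity shared variance of the generator."""
    cfg = design.PopulationConfig()
    dsn = _RatingDesign(cfg.repetitions)
    s_pop, s_sub = _spawn_seeds(seed, 2)
    rng = np.random.default_rng(s_sub)
    r2 = []
    for i in range(n_subjects):
        p = design.sample_population(cfg, seed=s_pop + i)[0]
        h, l, f = design.simulate_rating_values(
            p, dsn.latent, dsn.artificial, int(rng.integers(2 ** 31)))
        r2.append(np.corrcoef(l, f)[0, 1] ** 2)
    return {"mean_r2_likability_familiarity": float(np.mean(r2)),
            "n_subjects": n_subjects}


# ---------------------------------------------------------------------------
# choice model recovery
# ---------------------------------------------------------------------------

def choice_recovery_study(n_subjects: int = 500, seed: int = 0) -> dict:
    """Refit the logistic choice model on simulated subjects.

    Reports per-coefficient 95% Wald-CI coverage of the generating betas,
    plus the population mean classification accuracy and McFadden
    pseudo-R^2 of the refits.
    """
    cfg = design.PopulationConfig()
    dsn = _RatingDesign(cfg.repetitions)
    _, choice_trials = design.build_choice_design(dsn.stimuli,
                                                  cfg.trials_per_contrast, seed=0)
    s_pop, s_sub = _spawn_seeds(seed, 2)
    rng = np.random.default_rng(s_sub)
    coverage = np.zeros(4)
    accs, pr2s, ridge = [], [], 0
    for i in range(n_subjects):
        p = design.sample_population(cfg, seed=s_pop + i)[0]
        h, l, f = design.simulate_rating_values(
            p, dsn.latent, dsn.artificial, int(rng.integers(2 ** 31)))
        means = pd.DataFrame({"stimulus": dsn.stim_ids,
                              "likability": dsn.stimulus_mean(l),
                              "familiarity": dsn.stimulus_mean(f),
                              "humanlikeness": dsn.stimulus_mean(h)})
        filled = design.simulate_choices(p, choice_trials, means,
                                         seed=int(rng.integers(2 ** 31)))
        dsg = choicemodel.choice_design_frame(filled, means)
        model = choicemodel.fit_choice_logistic(dsg)
        true = np.asarray(p.betas)
        coverage += (model.ci_lower <= true) & (true <= model.ci_upper)
        accs.append(model.accuracy)
        pr2s.append(model.pseudo_r2)
        ridge += model.ridge_stabilized
    return {
        "ci_coverage": (coverage / n_subjects).tolist(),
        "min_ci_coverage": float(np.min(coverage / n_subjects)),
        "mean_accuracy": float(np.mean(accs)),
        "mean_pseudo_r2": float(np.mean(pr2s)),
        "ridge_stabilized_fraction": ridge / n_subjects,
        "n_subjects": n_subjects,
    }


def psychometric_slope_study(n_trials: int = 5000, true_slope: float = 2.0,
                             true_bias: float = 0.0, seed: int = 0) -> dict:
    """Recover a known psychometric logit from binary choices."""
    rng = np.random.default_rng(seed)
    dv = rng.standard_normal(n_trials)
    y = (rng.random(n_trials) < expit(true_bias + true_slope * dv)).astype(float)
    fit = choicemodel.psychometric_curve(dv, y, n_bins=8)
    return {"true_slope": true_slope, "fitted_slope": fit.logit_slope,
            "relative_error": abs(fit.logit_slope - true_slope) / true_slope,
            "n_trials": n_trials}


# ---------------------------------------------------------------------------
# linear-nonlinear recovery
# ---------------------------------------------------------------------------

def lnl_recovery_study(n_replicates: int = 500, seed: int = 0,
                       trials_per_category: int = 12) -> dict:
    """Recover region parameters and the VMPFC reconstruction under noise.

    Patterns are category means over ``trials_per_category`` noisy trials
    at the default amplitude noise.  Also verifies exact noiseless
    recovery and that the minimum of the computed (TPJ x FFG) pattern
    falls on artificial humans when the FFG dip term is active.
    """
    cats = design.DEFAULT_CATEGORIES
    h = np.array([c.latent_humanlikeness for c in cats])
    human = np.array([c.is_human for c in cats])
    params = lnl.LNLParams()
    true = {r: lnl.lnl_predict(params, r, h, human) for r in lnl.REGIONS}

    fit0 = lnl.fit_lnl(true, h, human)
    noiseless_err = max(
        abs(fit0.tpj.intercept - params.tpj.intercept),
        abs(fit0.tpj.slope - params.tpj.slope),
        abs(fit0.ffg.nonhuman_intercept - params.ffg.nonhuman_intercept),
        abs(fit0.ffg.nonhuman_slope - params.ffg.nonhuman_slope),
        abs(fit0.ffg.human_level - params.ffg.human_level),
        abs(fit0.dmpfc.baseline - params.dmpfc.baseline),
        abs(fit0.dmpfc.step - params.dmpfc.step),
        abs(fit0.vmpfc.gain - params.vmpfc.gain),
        abs(fit0.vmpfc.offset - params.vmpfc.offset),
    )

    se = design.SubjectParams().amplitude_noise_sd / np.sqrt(trials_per_category)
    rng = np.random.default_rng(seed)
    rs, min_art = [], 0
    errors: dict[str, list] = {k: [] for k in
                               ("tpj_intercept", "tpj_slope", "ffg_intercept",
                                "ffg_slope", "ffg_human_level", "vmpfc_gain",
                                "vmpfc_offset")}
    generating = {"tpj_intercept": params.tpj.intercept,
                  "tpj_slope": params.tpj.slope,
                  "ffg_intercept": params.ffg.nonhuman_intercept,
                  "ffg_slope": params.ffg.nonhuman_slope,
                  "ffg_human_level": params.ffg.human_level,
                  "vmpfc_gain": params.vmpfc.gain,
                  "vmpfc_offset": params.vmpfc.offset}
    for _ in range(n_replicates):
        pat = {r: true[r] + se * rng.standard_normal(len(cats))
               for r in lnl.REGIONS}
        fit = lnl.fit_lnl(pat, h, human)
        computed, r = lnl.reconstruct_vmpfc(pat["TPJ"], pat["FFG"], pat["VMPFC"])
        rs.append(r)
        min_art += int(np.argmin(computed)) == 3       # artificial_human index
        errors["tpj_intercept"].append(abs(fit.tpj.intercept - params.tpj.intercept))
        errors["tpj_slope"].append(abs(fit.tpj.slope - params.tpj.slope))
        errors["ffg_intercept"].append(
            abs(fit.ffg.nonhuman_intercept - params.ffg.nonhuman_intercept))
        errors["ffg_slope"].append(abs(fit.ffg.nonhuman_slope - params.ffg.nonhuman_slope))
        errors["ffg_human_level"].append(abs(fit.ffg.human_level - params.ffg.human_level))
        errors["vmpfc_gain"].append(abs(fit.vmpfc.gain - params.vmpfc.gain))
        errors["vmpfc_offset"].append(abs(fit.vmpfc.offset - params.vmpfc.offset))

    no_dip = lnl.LNLParams(ffg=lnl.FFGParams(params.ffg.nonhuman_intercept, 0.0,
                                             params.ffg.human_level))
    pattern_no_dip = lnl.lnl_predict(no_dip, "VMPFC", h, human)
    return {
        "noiseless_max_error": float(noiseless_err),
        "reconstruction_r_rate": float(np.mean(np.asarray(rs) >= 0.7)),
        "mean_reconstruction_r": float(np.mean(rs)),
        "min_at_artificial_rate": min_art / n_replicates,
        "min_at_artificial_without_dip": bool(int(np.argmin(pattern_no_dip)) == 3),
        "median_relative_errors": {
            k: float(np.median(v) / abs(generating[k])) for k, v in errors.items()},
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# BOLD signal chain
# ---------------------------------------------------------------------------

def signal_chain_study(n_replicates: int = 500, seed: int = 0,
                       n_trials: int = 36, window: tuple = (4.0, 7.0)) -> dict:
    """simulate_bold -> preprocess -> timepoint_glm recovery.

    Two known regressor weights drive per-trial amplitudes; each noisy
    replicate's window-mean coefficients are compared against the same
    pipeline run on the noise-free series (rescaled by the normalisation
    ratio), giving an exact conditional-unbiasedness reference.  Reports
    the z score of the mean difference per regressor and the sign/rank
    agreement of the recovered weights.
    """
    hrf = roistats.canonical_hrf(0.1)
    weights = np.array([0.8, -0.4])
    s_onset, s_noise = _spawn_seeds(seed, 2)
    onsets = design.build_onsets(n_trials, seed=s_onset)
    duration = onsets[-1] + 30.0
    rng = np.random.default_rng(s_noise)
    diffs, betas = [], []
    for _ in range(n_replicates):
        X = rng.standard_normal((n_trials, 2))
        amps = X @ weights + 0.3 * rng.standard_normal(n_trials)
        bseed = int(rng.integers(2 ** 31))
        noisy = design.simulate_bold(amps, onsets, 2.0, duration, hrf,
                                     noise_sd=1.0, seed=bseed,
                                     drift_amplitude=0.5)
        clean = design.simulate_bold(amps, onsets, 2.0, duration, hrf,
                                     noise_sd=0.0, drift_amplitude=0.5)
        ep = roistats.preprocess_timecourse(noisy.series, 2.0, onsets)
        ep0 = roistats.preprocess_timecourse(clean.series, 2.0, onsets)
        regs = pd.DataFrame({"r1": X[:, 0], "r2": X[:, 1]})
        eff = roistats.timepoint_glm(ep, regs, standardize=False)
        eff0 = roistats.timepoint_glm(ep0, regs, standardize=False)
        scale = ep0.norm_sd / ep.norm_sd
        b = np.array([eff.window_mean(n, window) for n in ("r1", "r2")])
        b0 = scale * np.array([eff0.window_mean(n, window) for n in ("r1", "r2")])
        diffs.append(b - b0)
        betas.append(b)
    diffs = np.asarray(diffs)
    betas = np.asarray(betas)
    se = diffs.std(axis=0, ddof=1) / np.sqrt(n_replicates)
    z = diffs.mean(axis=0) / se
    mean_b = betas.mean(axis=0)
    return {
        "bias_z": z.tolist(),
        "max_abs_bias_z": float(np.max(np.abs(z))),
        "mean_recovered": mean_b.tolist(),
        "sign_correct": bool(np.all(np.sign(mean_b) == np.sign(weights))),
        "rank_correct": bool(np.argsort(np.abs(mean_b)).tolist()
                             == np.argsort(np.abs(weights)).tolist()),
        "n_replicates": n_replicates,
    }


def sinc_oracle_error(n: int = 300, tr: float = 2.0, factor: int = 10,
                      freq: float = 0.1, phase: float = 0.3) -> float:
    """Max abs error of sinc oversampling against the analytic sinusoid,
    excluding the kernel half-width at each edge."""
    t = np.arange(n) * tr
    x = np.sin(2 * np.pi * freq * t + phase)
    fine = roistats.sinc_oversample(x, factor)
    tf = np.arange(n * factor) * tr / factor
    ref = np.sin(2 * np.pi * freq * tf + phase)
    guard = 32 * factor
    return float(np.max(np.abs(fine[guard:-guard] - ref[guard:-guard])))


def loso_null_study(n_replicates: int = 500, n_subjects: int = 21,
                    n_loci: int = 10, seed: int = 0) -> dict:
    """LOSO extraction is unbiased under a global null; naive peak
    selection on the same data is biased upward."""
    rng = np.random.default_rng(seed)
    loso_means, naive_means = [], []
    for _ in range(n_replicates):
        maps = rng.standard_normal((n_subjects, n_loci))
        vals, _ = roistats.loso_extract(maps, select="max")
        nvals, _ = roistats.naive_extract(maps, select="max")
        loso_means.append(vals.mean())
        naive_means.append(nvals.mean())
    loso_means = np.asarray(loso_means)
    naive_means = np.asarray(naive_means)
    z = loso_means.mean() / (loso_means.std(ddof=1) / np.sqrt(n_replicates))
    nz = naive_means.mean() / (naive_means.std(ddof=1) / np.sqrt(n_replicates))
    return {"loso_mean": float(loso_means.mean()), "loso_bias_z": float(z),
            "naive_mean": float(naive_means.mean()), "naive_bias_z": float(nz),
            "n_replicates": n_replicates}


# ---------------------------------------------------------------------------
# closed-form / brute-force oracles
# ---------------------------------------------------------------------------

def oracle_checks(seed: int = 0) -> dict:
    """Agreement of the package's core computations with independent
    oracles on small instances.

    * OLS line vs a hand normal-equations solve;
    * logistic likelihood at the MLE vs a coarse brute-force beta grid;
    * summed-window AIC vs the 2k + n log(RSS/n) formula applied by hand;
    * Pearson r vs its closed-form sum formula on a 4-pair toy set;
    * one-sample t vs the closed form on a 5-number sample.
    """
    rng = np.random.default_rng(seed)

    # OLS vs normal equations
    x = rng.standard_normal(10)
    y = 1.5 + 0.7 * x + 0.1 * rng.standard_normal(10)
    slope, intercept = _ols_line(x, y)
    A = np.column_stack([x, np.ones(10)])
    beta_ne = np.linalg.solve(A.T @ A, A.T @ y)
    ols_err = max(abs(slope - beta_ne[0]), abs(intercept - beta_ne[1]))

    # logistic MLE vs brute-force grid
    n = 40
    d = rng.standard_normal((n, 3)) * np.array([1.0, 0.8, 0.6])
    true_b = np.array([0.2, -1.0, -0.4, -0.5])
    eta = true_b[0] + d @ true_b[1:]
    yb = (rng.random(n) < expit(eta)).astype(float)
    dsg = pd.DataFrame({"dlik": d[:, 0], "dfam": d[:, 1], "dhum": d[:, 2], "y": yb})
    model = choicemodel.fit_choice_logistic(dsg)

    def loglik(b):
        mu = expit(b[0] + d @ b[1:])
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        return float(yb @ np.log(mu) + (1 - yb) @ np.log(1 - mu))

    grid = np.linspace(-3, 3, 9)
    best = -np.inf
    for b0 in grid:
        for b1 in grid:
            for b2 in grid:
                for b3 in grid:
                    best = max(best, loglik(np.array([b0, b1, b2, b3])))
    logit_margin = model.loglik - best          # >= 0 iff MLE beats the grid

    # AIC formula
    rss, nn, k = 3.7, 24, 5
    aic_err = abs(roistats.aic(rss, nn, k) - (2 * k + nn * np.log(rss / nn)))

    # Pearson closed form on a 4-pair toy set
    a = np.array([1.0, 2.0, 4.0, 7.0])
    b = np.array([2.0, 1.0, 5.0, 9.0])
    r_pkg = stats.pearsonr(a, b).statistic
    r_hand = (np.sum((a - a.mean()) * (b - b.mean()))
              / np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)))
    pearson_err = abs(r_pkg - r_hand)

    # one-sample t closed form on a 5-number sample
    sample = np.array([0.3, 0.9, -0.2, 1.1, 0.5])
    t_pkg = stats.ttest_1samp(sample, 0.0).statistic
    t_hand = sample.mean() / (sample.std(ddof=1) / np.sqrt(5))
    t_err = abs(t_pkg - t_hand)

    return {"ols_vs_normal_equations": float(ols_err),
            "logistic_loglik_margin_over_grid": float(logit_margin),
            "aic_formula_error": float(aic_err),
            "pearson_formula_error": float(pearson_err),
            "t_formula_error": float(t_err)}


# ---------------------------------------------------------------------------
# default-population behavioral summary
# ---------------------------------------------------------------------------

def default_population_summary(seed: int = 0) -> dict:
    """One default 21-subject population through the full behavioral
    analysis: group UV statistics, choice-model summaries and the cubic
    fit of the pooled likability/humanlikeness cloud."""
    cfg = design.PopulationConfig()
    dsn = _RatingDesign(cfg.repetitions)
    _, choice_trials = design.build_choice_design(dsn.stimuli,
                                                  cfg.trials_per_contrast, seed=0)
    s_pop, s_sub = _spawn_seeds(seed, 2)
    pop = design.sample_population(cfg, seed=s_pop)
    rng = np.random.default_rng(s_sub)
    depths, accs, pr2s, choice_depths = [], [], [], []
    pooled_h, pooled_l = [], []
    n_subject_sig = 0
    for p in pop:
        h, l, f = design.simulate_rating_values(
            p, dsn.latent, dsn.artificial, int(rng.integers(2 ** 31)))
        means = pd.DataFrame({"stimulus": dsn.stim_ids,
                              "category": dsn.stim_category,
                              "likability": dsn.stimulus_mean(l),
                              "familiarity": dsn.stimulus_mean(f),
                              "humanlikeness": dsn.stimulus_mean(h)})
        res = uvquant.uv_depth(means)
        depths.append(res.uv_depth)
        trials_df = design.ratings_frame(dsn.trials).assign(
            likability=l, familiarity=f, humanlikeness=h)
        dev = uvquant.presentation_deviations(trials_df, res)
        if stats.ttest_1samp(dev, 0.0).pvalue < 0.05:
            n_subject_sig += 1
        pooled_h.append(dsn.stimulus_mean(h))
        pooled_l.append(dsn.stimulus_mean(l))
        filled = design.simulate_choices(p, choice_trials, means,
                                         seed=int(rng.integers(2 ** 31)))
        dsg = choicemodel.choice_design_frame(filled, means)
        model = choicemodel.fit_choice_logistic(dsg)
        accs.append(model.accuracy)
        pr2s.append(model.pseudo_r2)
        dv = choicemodel.decision_variable(dsg, model)
        cat_h = {c: float(np.mean([mh for mh, sc in
                                   zip(dsn.stimulus_mean(h), dsn.stim_category)
                                   if sc == c]))
                 for c in dict.fromkeys(dsn.stim_category)}
        choice_depths.append(
            choicemodel.choice_uv_depth(dsg, dv, cat_h).choice_uv_depth)
    group = stats.ttest_1samp(depths, 0.0)
    cubic = uvquant.cubic_uv_fit(np.concatenate(pooled_h), np.concatenate(pooled_l))
    choice_t = stats.ttest_1samp(choice_depths, 0.0)
    return {
        "mean_uv_depth": float(np.mean(depths)),
        "group_t": float(group.statistic), "group_p": float(group.pvalue),
        "n_subjects_significant": n_subject_sig,
        "n_subjects": len(pop),
        "classification_accuracy_pct": float(100 * np.mean(accs)),
        "pseudo_r2": float(np.mean(pr2s)),
        "cubic_r_squared": float(cubic.r_squared),
        "mean_choice_uv_depth": float(np.mean(choice_depths)),
        "choice_uv_t": float(choice_t.statistic),
        "choice_uv_p": float(choice_t.pvalue),
    }
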