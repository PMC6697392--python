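"""ROI time-course statistical machinery.

The analysis chain mirrors the standard event-related ROI workflow:

1. :func:`canonical_hrf` — double-gamma hemodynamic response function
   (peak delay 6 s, undershoot delay 16 s, unit dispersions, undershoot
   ratio 1/6; peak normalised to 1).
2. :func:`preprocess_timecourse` — discrete-cosine high-pass at a 128 s
   cutoff period, z-normalisation, x10 sinc oversampling (windowed kernel,
   reflective padding) and epoching into a trials x time matrix.
3. :func:`timepoint_glm` — per-timepoint OLS across trials with
   standardized coefficients, no orthogonalisation; variance inflation
   factors computed once on the trial-level design.
4. :func:`model_select_aic` — Gaussian-likelihood AIC comparison of the
   three-rating GLM against the GLM extended with a binary human-detection
   regressor; the extension is accepted only if AIC improves *and* the
   human-detection group effect is significant.
5. :func:`loso_extract` — leave-one-subject-out effect extraction: the
   selection statistic for subject s is computed on all other subjects, so
   the extracted estimate is independent of the selection (no circularity
   bias).  :func:`naive_extract` is provided as the biased contrast.
6. :func:`across_subject_association` — Pearson correlation plus robust
   (Huber IRLS) regression, judged at Bonferroni-adjusted alphas (0.0125
   for rating-UV contexts, 0.0167 for choice-UV contexts).
7. :func:`ppi_analysis` — psychophysiological interaction in the
   convolution domain: the psychological contrast is expanded to event
   amplitudes, convolved with the HRF and multiplied with the seed series.

Group inference throughout is random-effects: per-subject coefficients
entered into two-sided one-sample t tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

__all__ = [
    "HRF", "ROITimecourse", "EffectTimecourse", "GroupEffect",
    "ModelSelection", "AssociationResult", "PPIResult",
    "CollinearRegressorsError",
    "canonical_hrf", "events_to_series", "dct_highpass", "sinc_oversample",
    "preprocess_timecourse", "timepoint_glm", "group_effect_tests",
    "aic", "model_select_aic", "loso_extract", "naive_extract",
    "across_subject_association", "ppi_analysis",
]

ALPHA_BY_CONTEXT = {"default": 0.05, "rating_uv": 0.0125, "choice_uv": 0.0167}


class CollinearRegressorsError(ValueError):
    """Raised when a design contains exactly collinear regressors."""


# ---------------------------------------------------------------------------
# hemodynamic response
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HRF:
    """Sampled canonical HRF; ``values[0]`` is 0 and the peak is 1."""

    grid: np.ndarray          # seconds, starting at 0
    values: np.ndarray
    parameters: dict = field(default_factory=dict)

    @property
    def resolution(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def __call__(self, t) -> np.ndarray:
        """Evaluate by linear interpolation; zero outside the support."""
        return np.interp(np.asarray(t, dtype=float), self.grid, self.values,
                         left=0.0, right=0.0)


def canonical_hrf(resolution: float = 0.1, peak_delay: float = 6.0,
                  undershoot_delay: float = 16.0, peak_dispersion: float = 1.0,
                  undershoot_dispersion: float = 1.0,
                  undershoot_ratio: float = 1.0 / 6.0,
                  length: float = 32.0) -> HRF:
    """Canonical double-gamma HRF.

    ``h(t) = g(t; peak_delay, disp) - ratio * g(t; undershoot_delay, disp)``
    with gamma-density components; the peak is rescaled to amplitude 1.
    With the default shape parameters the analytic mode of the dominant
    component is ``(peak_delay - dispersion) = 5 s`` on the gamma-density
    parameterisation used here (shape ``delay/disp``, scale ``disp``).
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    t = np.arange(0.0, length + resolution / 2, resolution)
    peak = stats.gamma.pdf(t, a=peak_delay / peak_dispersion,
                           scale=peak_dispersion)
    under = stats.gamma.pdf(t, a=undershoot_delay / undershoot_dispersion,
                            scale=undershoot_dispersion)
    values = peak - undershoot_ratio * under
    values = values / values.max()
    params = dict(peak_delay=peak_delay, undershoot_delay=undershoot_delay,
                  peak_dispersion=peak_dispersion,
                  undershoot_dispersion=undershoot_dispersion,
                  undershoot_ratio=undershoot_ratio, length=length)
    return HRF(grid=t, values=values, parameters=params)


def events_to_series(amplitudes, onsets, tr: float, n_samples: int,
                     hrf: HRF) -> np.ndarray:
    """Noiseless BOLD series: sum of amplitude-scaled HRFs at event onsets.

    Linear in the amplitudes by construction.
    """
    amps = np.asarray(amplitudes, dtype=float)
    ons = np.asarray(onsets, dtype=float)
    t = np.arange(n_samples) * tr
    series = np.zeros(n_samples)
    for a, o in zip(amps, ons):
        series += a * hrf(t - o)
    return series


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def dct_highpass(series: np.ndarray, tr: float, cutoff: float = 128.0) -> np.ndarray:
    """Remove slow drift by projecting out a discrete-cosine basis.

    All cosine regressors with period longer than ``cutoff`` seconds (plus
    the constant) are regressed out, the convention of SPM-style high-pass
    filtering.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if cutoff <= 2 * tr:
        raise ValueError("cutoff period must exceed 2*TR")
    order = int(np.floor(2.0 * n * tr / cutoff))
    demeaned = x - x.mean()
    if order < 1:
        return demeaned
    k = np.arange(1, order + 1)
    grid = np.pi * (np.arange(n) + 0.5) / n
    basis = np.cos(np.outer(grid, k))          # n x order, orthogonal DCT-II
    basis /= np.sqrt((basis ** 2).sum(axis=0))
    return demeaned - basis @ (basis.T @ demeaned)


def sinc_oversample(series: np.ndarray, factor: int = 10,
                    half_width: int = 32) -> np.ndarray:
    """Windowed-sinc interpolation onto a ``factor``-times finer grid.

    Polyphase evaluation of a Blackman-windowed sinc kernel with
    ``half_width`` coarse-sample taps on each side; the input is padded by
    reflection, so the ``half_width`` samples nearest each edge are
    approximate.  Output sample ``k*factor`` equals a filtered estimate of
    input sample ``k``; length is ``len(series) * factor``.
    """
    x = np.asarray(series, dtype=float)
    if factor < 1:
        raise ValueError("oversample factor must be >= 1")
    if factor == 1:
        return x.copy()
    n = x.size
    if n <= half_width:
        raise ValueError("series shorter than interpolation kernel")
    w = half_width
    xpad = np.concatenate([x[w:0:-1], x, x[-2:-w - 2:-1]])
    m = np.arange(-w, w + 1)
    out = np.empty(n * factor)
    for p in range(factor):
        tau = p / factor - m                       # offsets of taps from target
        kernel = np.sinc(tau) * (0.42 + 0.5 * np.cos(np.pi * tau / w)
                                 + 0.08 * np.cos(2 * np.pi * tau / w))
        kernel /= kernel.sum()
        out[p::factor] = np.convolve(xpad, kernel[::-1], mode="valid")
    return out


@dataclass(frozen=True)
class ROITimecourse:
    """Epoched, preprocessed ROI activity: a trials x time matrix."""

    matrix: np.ndarray
    tr_effective: float
    epoch_window: tuple[float, float]
    times: np.ndarray                 # seconds relative to onset
    norm_sd: float                    # SD removed by z-normalisation
    constant_input: bool = False

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0]


def preprocess_timecourse(series, tr: float, onsets,
                          cutoff: float = 128.0, oversample: int = 10,
                          epoch_window: tuple[float, float] = (0.0, 12.0)
                          ) -> ROITimecourse:
    """Full-session preprocessing and epoching.

    High-pass filter (DCT, cutoff period in seconds), z-normalise the full
    session, sinc-oversample, then cut epochs around each onset.  A
    constant input yields an all-zero output with the ``constant_input``
    flag set (z-normalising zeros is undefined).
    """
    x = np.asarray(series, dtype=float)
    ons = np.asarray(onsets, dtype=float)
    duration = x.size * tr
    if np.any(ons < 0) or np.any(ons >= duration):
        raise ValueError("onsets outside session")
    if np.any(np.diff(ons) < 0):
        raise ValueError("onsets must be sorted")
    filtered = dct_highpass(x, tr, cutoff)
    sd = float(filtered.std())
    # "constant" up to floating-point residue of the basis projection
    constant = sd <= 1e-10 * max(1.0, float(np.abs(x).max()))
    z = np.zeros_like(filtered) if constant else filtered / sd
    fine = sinc_oversample(z, oversample)
    dt = tr / oversample
    w0, w1 = epoch_window
    n_time = int(round((w1 - w0) / dt)) + 1
    rows = []
    for o in ons:
        i0 = int(round((o + w0) / dt))
        if i0 < 0 or i0 + n_time > fine.size:
            raise ValueError(f"epoch for onset {o} s extends outside session")
        rows.append(fine[i0:i0 + n_time])
    times = w0 + dt * np.arange(n_time)
    return ROITimecourse(matrix=np.asarray(rows), tr_effective=dt,
                         epoch_window=(w0, w1), times=times,
                         norm_sd=sd, constant_input=constant)


# ---------------------------------------------------------------------------
# per-timepoint GLM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectTimecourse:
    """Per-regressor coefficient at every oversampled timepoint."""

    names: tuple[str, ...]
    coefficients: np.ndarray          # n_time x n_regressors
    times: np.ndarray
    tr_effective: float
    vif: dict[str, float]
    standardized: bool = True

    def window_mean(self, name: str, window: tuple[float, float]) -> float:
        j = self.names.index(name)
        m = (self.times >= window[0]) & (self.times <= window[1])
        return float(self.coefficients[m, j].mean())


def _design_matrix(regressors: pd.DataFrame) -> tuple[np.ndarray, tuple[str, ...]]:
    names = tuple(regressors.columns)
    X = regressors.to_numpy(dtype=float)
    X = X - X.mean(axis=0)            # regressors enter mean-centered
    return X, names


def design_vifs(regressors: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factors of the trial-level design.

    VIF_j = 1 / (1 - R^2_j) from regressing regressor j on the others;
    exact collinearity gives an infinite VIF.
    """
    X, names = _design_matrix(regressors)
    out = {}
    for j, name in enumerate(names):
        xj = X[:, j]
        others = np.delete(X, j, axis=1)
        if others.shape[1] == 0:
            out[name] = 1.0
            continue
        A = np.column_stack([others, np.ones(len(xj))])
        coef, *_ = np.linalg.lstsq(A, xj, rcond=None)
        resid = xj - A @ coef
        sst = float(xj @ xj)
        r2 = 0.0 if sst == 0.0 else 1.0 - float(resid @ resid) / sst
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def timepoint_glm(epochs: ROITimecourse, regressors: pd.DataFrame,
                  standardize: bool = True) -> EffectTimecourse:
    """Fit one OLS across trials at every oversampled timepoint.

    All regressors compete for variance (no orthogonalisation).  With
    ``standardize`` the coefficients are rescaled to standardized betas
    (beta * sd(x) / sd(y) per timepoint).  Exactly collinear designs are
    refused with the offending regressor named.
    """
    X, names = _design_matrix(regressors)
    if X.shape[0] != epochs.n_trials:
        raise ValueError("regressor rows must match epoch trials")
    vifs = design_vifs(regressors)
    bad = [n for n, v in vifs.items() if not np.isfinite(v)]
    if bad:
        raise CollinearRegressorsError(
            f"exactly collinear regressor(s): {', '.join(bad)}")
    Y = epochs.matrix                                    # trials x time
    Yc = Y - Y.mean(axis=0, keepdims=True)
    coefs, *_ = np.linalg.lstsq(X, Yc, rcond=None)       # p x time
    coefs = coefs.T                                      # time x p
    if standardize:
        sx = X.std(axis=0)
        sy = Y.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            coefs = np.where(sy[:, None] > 0, coefs * sx[None, :] / sy[:, None], 0.0)
    return EffectTimecourse(names=names, coefficients=coefs, times=epochs.times,
                            tr_effective=epochs.tr_effective, vif=vifs,
                            standardized=standardize)


@dataclass(frozen=True)
class GroupEffect:
    """Across-subject effect-size time courses with per-timepoint t tests."""

    names: tuple[str, ...]
    mean: np.ndarray                  # n_time x p
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    times: np.ndarray
    n_subjects: int


def group_effect_tests(effects: list[EffectTimecourse]) -> GroupEffect:
    """Random-effects stage: one-sample t tests of per-subject coefficients."""
    names = effects[0].names
    stack = np.stack([e.coefficients for e in effects])   # subj x time x p
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    se = stack.std(axis=0, ddof=1) / np.sqrt(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, mean / se, np.nan)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    return GroupEffect(names=names, mean=mean, se=se, t=t, p=p,
                       times=effects[0].times, n_subjects=n)


# ---------------------------------------------------------------------------
# AIC model selection
# ---------------------------------------------------------------------------

def aic(rss: float, n: int, k: int) -> float:
    """Gaussian-likelihood AIC up to an additive constant: 2k + n log(RSS/n)."""
    return 2.0 * k + n * np.log(rss / n)


def _window_aic(epochs: ROITimecourse, regressors: pd.DataFrame,
                window: tuple[float, float]) -> float:
    """Summed per-timepoint AIC of the trials-by-time GLM over the window."""
    X, _ = _design_matrix(regressors)
    A = np.column_stack([X, np.ones(X.shape[0])])
    m = (epochs.times >= window[0]) & (epochs.times <= window[1])
    Y = epochs.matrix[:, m]
    coef, *_ = np.linalg.lstsq(A, Y, rcond=None)
    resid = Y - A @ coef
    rss = (resid ** 2).sum(axis=0)
    n = Y.shape[0]
    k = A.shape[1]
    return float(np.sum([aic(r, n, k) for r in rss]))


@dataclass(frozen=True)
class ModelSelection:
    """Outcome of the human-detection model comparison."""

    accepted: bool                    # extended model selected
    aic_base: float
    aic_extended: float
    candidate: str
    group_t: float
    group_p: float
    window: tuple[float, float]
    subject_aic_base: np.ndarray = field(repr=False, default=None)
    subject_aic_extended: np.ndarray = field(repr=False, default=None)


def model_select_aic(subject_epochs: list[ROITimecourse],
                     subject_regressors: list[pd.DataFrame],
                     candidate: str = "human_detection",
                     window: tuple[float, float] = (2.0, 8.0),
                     alpha: float = 0.05) -> ModelSelection:
    """Accept the human-detection-extended GLM only on joint evidence.

    Per subject, the base GLM (all regressors except ``candidate``) and the
    extended GLM are scored by Gaussian AIC summed over the analysis
    window.  The extension is accepted iff total AIC decreases *and* the
    candidate's group-level effect (window-mean standardized coefficient,
    one-sample t across subjects) is significant at ``alpha``.
    """
    a_base, a_ext, cand_coef = [], [], []
    for ep, regs in zip(subject_epochs, subject_regressors):
        if candidate not in regs.columns:
            raise ValueError(f"candidate regressor {candidate!r} missing")
        base = regs.drop(columns=[candidate])
        a_base.append(_window_aic(ep, base, window))
        a_ext.append(_window_aic(ep, regs, window))
        eff = timepoint_glm(ep, regs)
        cand_coef.append(eff.window_mean(candidate, window))
    a_base = np.asarray(a_base)
    a_ext = np.asarray(a_ext)
    coefs = np.asarray(cand_coef)
    res = stats.ttest_1samp(coefs, 0.0)
    accepted = bool(a_ext.sum() < a_base.sum() and res.pvalue < alpha)
    return ModelSelection(accepted=accepted, aic_base=float(a_base.sum()),
                          aic_extended=float(a_ext.sum()), candidate=candidate,
                          group_t=float(res.statistic), group_p=float(res.pvalue),
                          window=window, subject_aic_base=a_base,
                          subject_aic_extended=a_ext)


# ---------------------------------------------------------------------------
# leave-one-subject-out extraction
# ---------------------------------------------------------------------------

def loso_extract(effect_maps: np.ndarray, select: str = "max"
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-subject-out effect extraction.

    ``effect_maps`` is subjects x loci (candidate coordinates or
    timepoints).  For each subject s, the selection statistic — the mean
    map over all *other* subjects — picks a locus (``"max"``: peak;
    ``"absmax"``: peak magnitude), and the effect is then read from
    subject s's own map at that locus.  n subjects means n refits.  The
    extracted estimates are independent of the selection, which removes
    the circularity bias of in-sample peak selection.
    """
    maps = np.asarray(effect_maps, dtype=float)
    n = maps.shape[0]
    if n < 3:
        raise ValueError("LOSO extraction needs >= 3 subjects")
    total = maps.sum(axis=0)
    values = np.empty(n)
    chosen = np.empty(n, dtype=int)
    for s in range(n):
        stat = (total - maps[s]) / (n - 1)
        j = int(np.argmax(np.abs(stat)) if select == "absmax" else np.argmax(stat))
        chosen[s] = j
        values[s] = maps[s, j]
    return values, chosen


def naive_extract(effect_maps: np.ndarray, select: str = "max"
                  ) -> tuple[np.ndarray, int]:
    """In-sample peak selection (the biased procedure LOSO replaces)."""
    maps = np.asarray(effect_maps, dtype=float)
    stat = maps.mean(axis=0)
    j = int(np.argmax(np.abs(stat)) if select == "absmax" else np.argmax(stat))
    return maps[:, j], j


# ---------------------------------------------------------------------------
# across-subject association
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationResult:
    pearson_r: float
    p: float
    robust_slope: float
    robust_p: float
    alpha_threshold: float
    significant: bool
    degenerate: bool = False


def across_subject_association(behavioral, neural,
                               context: str = "default") -> AssociationResult:
    """Behavioral-neural association across subjects.

    Pearson correlation (two-sided) plus a robust linear regression of the
    neural on the behavioral measure (IRLS with Huber weighting).  The
    significance threshold is Bonferroni-adjusted by analysis context:
    0.0125 when the behavioral rating-task UV depth is involved, 0.0167
    for the choice-task UV depth, 0.05 otherwise.
    """
    if context not in ALPHA_BY_CONTEXT:
        raise ValueError(f"unknown context {context!r}")
    alpha = ALPHA_BY_CONTEXT[context]
    b = np.asarray(behavioral, dtype=float)
    nvec = np.asarray(neural, dtype=float)
    if b.size < 3:
        raise ValueError("association needs >= 3 subjects")
    if np.ptp(b) == 0.0 or np.ptp(nvec) == 0.0:
        return AssociationResult(float("nan"), float("nan"), float("nan"),
                                 float("nan"), alpha, False, degenerate=True)
    r, p = stats.pearsonr(b, nvec)
    X = sm.add_constant(b)
    rlm = sm.RLM(nvec, X, M=sm.robust.norms.HuberT()).fit()
    slope = float(rlm.params[1])
    z = slope / float(rlm.bse[1])
    robust_p = float(2.0 * stats.norm.sf(abs(z)))
    return AssociationResult(pearson_r=float(r), p=float(p), robust_slope=slope,
                             robust_p=robust_p, alpha_threshold=alpha,
                             significant=bool(p < alpha))


# ---------------------------------------------------------------------------
# psychophysiological interaction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PPIResult:
    coefficient: float
    t: float
    p: float
    df: int


def ppi_analysis(seed_series, target_series, psych, onsets, tr: float,
                 hrf: HRF | None = None, convolve_psych: bool = True) -> PPIResult:
    """Convolution-domain psychophysiological interaction.

    The psychological contrast (one value per trial, mean-centered) is
    expanded to event amplitudes at the trial onsets and convolved with
    the HRF; the interaction regressor is its elementwise product with the
    seed series.  The target is regressed on {interaction, seed, convolved
    psych, constant} and the interaction coefficient is reported.  With
    ``convolve_psych=False`` the raw event-amplitude series is used
    instead (an exact-neural-series mode for simulated data where the
    neural series is known).  A constant psychological vector is refused:
    after centering it carries no signal and the interaction collapses
    onto the seed.
    """
    seed = np.asarray(seed_series, dtype=float)
    target = np.asarray(target_series, dtype=float)
    ps = np.asarray(psych, dtype=float)
    if seed.shape != target.shape:
        raise ValueError("seed and target series must be aligned")
    ps = ps - ps.mean()
    if np.allclose(ps, 0.0):
        raise CollinearRegressorsError(
            "constant psychological vector: interaction collinear with seed")
    n = seed.size
    if hrf is None:
        hrf = canonical_hrf(resolution=min(tr / 10.0, 0.1))
    if convolve_psych:
        psych_series = events_to_series(ps, onsets, tr, n, hrf)
    else:
        psych_series = np.zeros(n)
        idx = np.clip(np.round(np.asarray(onsets) / tr).astype(int), 0, n - 1)
        np.add.at(psych_series, idx, ps)
    interaction = psych_series * seed
    X = np.column_stack([interaction, seed, psych_series, np.ones(n)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearRegressorsError("collinear PPI design")
    coef, *_ = np.linalg.lstsq(X, target, rcond=None)
    resid = target - X @ coef
    dof = n - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    t_stat = float(coef[0] / np.sqrt(cov[0, 0]))
    p = float(2.0 * stats.t.sf(abs(t_stat), df=dof))
    return PPIResult(coefficient=float(coef[0]), t=t_stat, p=p, df=dof)
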