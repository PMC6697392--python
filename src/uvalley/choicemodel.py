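"""Modelling two-alternative choices between agents.

Choices are driven by relative rating attributes: for each trial the
difference (first minus second presented stimulus) in mean rated
likability, familiarity and humanlikeness.  A subject-wise multiple
logistic regression of the observed choice (y = 0 first, y = 1 second) on
these deltas yields weights b1..b3; the subject's **decision variable**

    dv = b1*dLikability + b2*dFamiliarity + b3*dHumanlikeness

(no constant term) is the weighted evidence for the second stimulus.  The
psychometric curve bins dv into equally populated bins and fits a
two-parameter logit; the **choice UV depth** regresses the mean unsigned
dv of each human-referenced contrast on the contrast's humanlikeness gap
and measures how much the human-vs-artificial-human contrast exceeds the
linear prediction (observed - predicted; positive = valley: the decision
between humans and artificial humans is more clear-cut than a
humanlikeness continuum implies).

Group inference is random-effects: per-subject coefficients entered into
one-sample t tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "DataConsistencyError", "DecisionModel", "DecisionVariableSeries",
    "PsychometricFit", "ChoiceUVResult",
    "relative_attributes", "choice_design_frame", "fit_choice_logistic",
    "decision_variable", "psychometric_curve", "choice_uv_depth",
    "group_beta_tests",
]

ATTRIBUTES = ("likability", "familiarity", "humanlikeness")


class DataConsistencyError(KeyError):
    """A choice trial references a stimulus without rating data."""


# ---------------------------------------------------------------------------
# relative attributes
# ---------------------------------------------------------------------------

def _means_lookup(rating_means) -> dict[str, np.ndarray]:
    if isinstance(rating_means, dict):
        return rating_means
    df = rating_means
    if "stimulus" in df.columns:
        df = df.set_index("stimulus")
    vals = df[list(ATTRIBUTES)].to_numpy(dtype=float)
    return dict(zip(df.index, vals))


def relative_attributes(trial, rating_means
                        ) -> tuple[float, float, float]:
    """(dLikability, dFamiliarity, dHumanlikeness), first minus second.

    ``rating_means`` may be a per-stimulus mean table or a prebuilt
    stimulus-id -> (likability, familiarity, humanlikeness) mapping.
    """
    lut = _means_lookup(rating_means)
    try:
        a = lut[trial.first.id]
        b = lut[trial.second.id]
    except KeyError as e:
        raise DataConsistencyError(f"no rating means for stimulus {e.args[0]!r}") from e
    d = a - b
    return float(d[0]), float(d[1]), float(d[2])


def choice_design_frame(choice_trials, rating_means) -> pd.DataFrame:
    """Trial table with deltas and observed choices, ready for fitting."""
    lut = _means_lookup(rating_means)
    rows = []
    for t in choice_trials:
        try:
            d = lut[t.first.id] - lut[t.second.id]
        except KeyError as e:
            raise DataConsistencyError(
                f"no rating means for stimulus {e.args[0]!r}") from e
        rows.append((t.contrast.label, d[0], d[1], d[2], t.choice))
    return pd.DataFrame(rows, columns=["contrast", "dlik", "dfam", "dhum", "y"])


# ---------------------------------------------------------------------------
# logistic decision model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecisionModel:
    """Subject-wise logistic choice model.

    ``betas`` are (b0, b1, b2, b3) on the log-odds scale for the
    likability, familiarity and humanlikeness deltas; ``pseudo_r2`` is
    McFadden's 1 - loglik/loglik_null; ``accuracy`` is the fraction of
    trials classified correctly at a 0.5 threshold.
    """

    betas: np.ndarray
    se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    pseudo_r2: float
    accuracy: float
    loglik: float
    loglik_null: float
    ridge_stabilized: bool = False

    @property
    def beta0(self): return float(self.betas[0])
    @property
    def beta1(self): return float(self.betas[1])
    @property
    def beta2(self): return float(self.betas[2])
    @property
    def beta3(self): return float(self.betas[3])


def _ridge_logit(X: np.ndarray, y: np.ndarray, alpha: float = 0.1,
                 maxiter: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Newton iterations for an L2-penalised logit (separation fallback).

    The intercept is not penalised; returns (betas, covariance) with the
    covariance taken from the penalised Hessian.
    """
    n, p = X.shape
    pen = alpha * np.eye(p)
    pen[0, 0] = 0.0
    beta = np.zeros(p)
    for _ in range(maxiter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1 - mu) + 1e-10
        grad = X.T @ (y - mu) - pen @ beta
        hess = (X * w[:, None]).T @ X + pen
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = X @ beta
    mu = expit(eta)
    w = mu * (1 - mu) + 1e-10
    hess = (X * w[:, None]).T @ X + pen
    return beta, np.linalg.inv(hess)


def fit_choice_logistic(design: pd.DataFrame, alpha_ridge: float = 0.1
                        ) -> DecisionModel:
    """Maximum-likelihood logistic fit of choice on the three deltas.

    Complete (or quasi-complete) separation is caught and refit with a
    small ridge penalty; the result carries the ``ridge_stabilized`` flag
    and a warning is emitted.
    """
    y = design["y"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(design)),
                         design[["dlik", "dfam", "dhum"]].to_numpy(dtype=float)])
    ridge = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")      # promote separation warnings
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        if (not res.mle_retvals.get("converged", False)
                or np.max(np.abs(res.params)) > 25.0):
            raise PerfectSeparationError("implausible coefficient magnitude")
        betas = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
        llf = float(res.llf)
    except (PerfectSeparationError, Warning, np.linalg.LinAlgError):
        warnings.warn("separation detected; ridge-stabilized logistic fit used",
                      stacklevel=2)
        ridge = True
        betas, cov = _ridge_logit(X, y, alpha=alpha_ridge)
        mu = expit(X @ betas)
        eps = 1e-12
        llf = float(y @ np.log(mu + eps) + (1 - y) @ np.log(1 - mu + eps))

    p_bar = y.mean()
    if p_bar in (0.0, 1.0):
        ll0 = 0.0
    else:
        ll0 = float(len(y) * (p_bar * np.log(p_bar)
                              + (1 - p_bar) * np.log(1 - p_bar)))
    pseudo = 1.0 - llf / ll0 if ll0 != 0.0 else float("nan")
    pred = expit(X @ betas) >= 0.5
    accuracy = float(np.mean(pred == (y == 1.0)))
    se = np.sqrt(np.diag(cov))
    z = stats.norm.ppf(0.975)
    return DecisionModel(betas=betas, se=se, ci_lower=betas - z * se,
                         ci_upper=betas + z * se, pseudo_r2=pseudo,
                         accuracy=accuracy, loglik=llf, loglik_null=ll0,
                         ridge_stabilized=ridge)


# ---------------------------------------------------------------------------
# decision variable and psychometric curve
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecisionVariableSeries:
    dv: np.ndarray
    abs_dv: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.abs_dv is None:
            object.__setattr__(self, "abs_dv", np.abs(self.dv))


def decision_variable(design: pd.DataFrame, model: DecisionModel,
                      include_intercept: bool = False) -> DecisionVariableSeries:
    """Per-trial decision variable: the weighted sum of deltas.

    The constant term is excluded by default (the decision variable is a
    stimulus comparison, not a response bias); ``include_intercept``
    offers the alternative for sensitivity analyses.
    """
    X = design[["dlik", "dfam", "dhum"]].to_numpy(dtype=float)
    dv = X @ model.betas[1:]
    if include_intercept:
        dv = dv + model.betas[0]
    return DecisionVariableSeries(dv=dv)


@dataclass(frozen=True)
class PsychometricFit:
    bin_edges: np.ndarray
    bin_dv: np.ndarray                 # mean dv per bin
    bin_choice_prob: np.ndarray
    bin_counts: np.ndarray
    logit_bias: float
    logit_slope: float

    def predict(self, dv) -> np.ndarray:
        return expit(self.logit_bias + self.logit_slope * np.asarray(dv, float))


def psychometric_curve(dv, y, n_bins: int = 8,
                       fit_level: str = "trial") -> PsychometricFit:
    """Equally populated dv bins with a two-parameter logit fit.

    Bin counts differ by at most one.  The logit (bias, slope) is fitted
    by maximum likelihood on trial-level data by default; with
    ``fit_level="bin"`` a binomial GLM on the bin proportions is used
    instead.
    """
    dv = np.asarray(dv, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if dv.size < n_bins:
        raise ValueError("fewer trials than bins")
    if np.ptp(dv) == 0.0:
        raise ValueError("cannot bin an all-identical decision variable")
    order = np.argsort(dv, kind="stable")
    chunks = np.array_split(order, n_bins)
    bin_dv = np.array([dv[c].mean() for c in chunks])
    bin_p = np.array([y[c].mean() for c in chunks])
    counts = np.array([len(c) for c in chunks])
    sorted_dv = dv[order]
    inner = [0.5 * (sorted_dv[np.cumsum(counts)[:-1] - 1]
                    + sorted_dv[np.cumsum(counts)[:-1]])]
    edges = np.concatenate([[sorted_dv[0]], *inner, [sorted_dv[-1]]])

    if fit_level == "trial":
        X = np.column_stack([np.ones_like(dv), dv])
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        bias, slope = res.params
    elif fit_level == "bin":
        successes = np.array([y[c].sum() for c in chunks])
        endog = np.column_stack([successes, counts - successes])
        X = np.column_stack([np.ones(n_bins), bin_dv])
        res = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
        bias, slope = res.params
    else:
        raise ValueError("fit_level must be 'trial' or 'bin'")
    return PsychometricFit(bin_edges=edges, bin_dv=bin_dv, bin_choice_prob=bin_p,
                           bin_counts=counts, logit_bias=float(bias),
                           logit_slope=float(slope))


# ---------------------------------------------------------------------------
# choice UV depth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChoiceUVResult:
    contrasts: tuple[str, ...]
    delta_dv: np.ndarray               # mean |dv| per contrast
    humanlikeness_gap: np.ndarray      # |category-mean humanlikeness difference|
    slope: float
    intercept: float
    predicted: float
    observed: float
    choice_uv_depth: float             # observed - predicted; positive = valley
    target_contrast: str


def choice_uv_depth(design: pd.DataFrame, dv_series: DecisionVariableSeries,
                    category_humanlikeness: dict[str, float],
                    reference: str = "human_no_impair",
                    target: str = "artificial_human") -> ChoiceUVResult:
    """Choice-task UV depth from the unsigned decision variable.

    Uses the contrasts referenced to ``reference`` (the five human
    contrasts by default): per contrast, delta_dv = mean |dv|; an OLS line
    of delta_dv on the absolute category-mean humanlikeness gap is fitted
    over the non-target contrasts and extrapolated to the
    reference-vs-target contrast.  depth = observed - predicted.
    """
    labels = design["contrast"].to_numpy()
    ref_prefix = f"{reference}_vs_"
    ref_labels = sorted({l for l in labels if l.startswith(ref_prefix)})
    if len(ref_labels) < 3:
        raise DataConsistencyError(
            f"need the {reference}-referenced contrasts in the design")
    target_label = f"{ref_prefix}{target}"
    if target_label not in ref_labels:
        raise DataConsistencyError(f"missing contrast {target_label!r}")
    abs_dv = dv_series.abs_dv
    ddv, gaps = [], []
    for lab in ref_labels:
        m = labels == lab
        other = lab[len(ref_prefix):]
        try:
            gap = abs(category_humanlikeness[reference]
                      - category_humanlikeness[other])
        except KeyError as e:
            raise DataConsistencyError(
                f"no humanlikeness mean for category {e.args[0]!r}") from e
        ddv.append(float(abs_dv[m].mean()))
        gaps.append(gap)
    ddv = np.asarray(ddv)
    gaps = np.asarray(gaps)
    fit_mask = np.array([l != target_label for l in ref_labels])
    x, yv = gaps[fit_mask], ddv[fit_mask]
    dx = x - x.mean()
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate humanlikeness gaps for the fit")
    slope = float(dx @ (yv - yv.mean()) / (dx @ dx))
    intercept = float(yv.mean() - slope * x.mean())
    i = ref_labels.index(target_label)
    predicted = intercept + slope * gaps[i]
    observed = float(ddv[i])
    return ChoiceUVResult(contrasts=tuple(ref_labels), delta_dv=ddv,
                          humanlikeness_gap=gaps, slope=slope,
                          intercept=intercept, predicted=predicted,
                          observed=observed,
                          choice_uv_depth=observed - predicted,
                          target_contrast=target_label)


# ---------------------------------------------------------------------------
# group stage
# ---------------------------------------------------------------------------

def group_beta_tests(models: list[DecisionModel], alpha: float = 0.05
                     ) -> pd.DataFrame:
    """One-sample t tests of per-subject betas across subjects."""
    stack = np.stack([m.betas for m in models])
    names = ["beta0", "beta1", "beta2", "beta3"]
    res = stats.ttest_1samp(stack, 0.0, axis=0)
    return pd.DataFrame({"coefficient": names,
                         "mean": stack.mean(axis=0),
                         "t": res.statistic, "p": res.pvalue,
                         "significant": res.pvalue < alpha})
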