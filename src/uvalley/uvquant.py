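"""Quantifying the uncanny valley (UV) from rating data.

The UV hypothesis holds that likability of an agent rises with its
humanlikeness but drops selectively for highly humanlike *artificial*
agents.  The central statistic here is **UV depth**: fit likability on
humanlikeness by ordinary least squares over all stimuli *except* the
UV-relevant target category, extrapolate the fit to the target's mean
humanlikeness, and subtract the target's observed mean likability.

    uv_depth = predicted_likability - observed_likability

Positive depth means the target is less liked than a linear humanlikeness
continuum predicts, i.e. it falls in the valley.  Two complementary
quantifications are provided: a leave-one-category-out residual profile
(each category's likability residual under a fit that excluded it) and a
third-order polynomial fit of the full likability/humanlikeness cloud.

All fits operate on per-stimulus subject-mean ratings; group inference is
random-effects (per-subject depths entered into one-sample t tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SingularFitError",
    "UVResult",
    "ResidualProfile",
    "CubicFit",
    "GroupUVTests",
    "uv_depth",
    "uv_depth_arrays",
    "uv_depth_residuals",
    "cubic_uv_fit",
    "group_uv_tests",
    "stimulus_means",
    "presentation_deviations",
]


class SingularFitError(ValueError):
    """Raised when a least-squares design is degenerate (zero x-variance or
    rank deficient)."""


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UVResult:
    """Linear-continuum UV quantification for one subject (or one pattern).

    ``uv_depth = predicted - observed`` in the units of the outcome
    (rating units for likability, arbitrary activity units for neural
    patterns); positive = valley.
    """

    slope: float
    intercept: float
    predicted: float
    observed: float
    uv_depth: float
    target_category: str
    n_points: int

    # backwards-friendly aliases used in reports
    @property
    def predicted_likability(self) -> float:
        return self.predicted

    @property
    def observed_likability(self) -> float:
        return self.observed


@dataclass(frozen=True)
class ResidualProfile:
    """Leave-one-category-out residuals, one entry per category.

    ``residuals[c]`` is mean(observed - predicted) for category ``c`` under
    the linear likability~humanlikeness fit estimated *without* category
    ``c``; a UV category shows the most negative residual.
    """

    categories: tuple[str, ...]
    residuals: np.ndarray
    fits: tuple[tuple[float, float], ...]  # (slope, intercept) per left-out category

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.categories, self.residuals.tolist()))

    def most_negative(self) -> str:
        return self.categories[int(np.argmin(self.residuals))]


@dataclass(frozen=True)
class CubicFit:
    """Third-order polynomial fit of likability on humanlikeness."""

    coefficients: np.ndarray  # c0..c3, ascending powers
    r_squared: float
    degenerate: bool = False

    def predict(self, x) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(x, dtype=float),
                                                self.coefficients)


@dataclass(frozen=True)
class GroupUVTests:
    """Group and per-subject UV inference.

    Group stage: one-sample t test of per-subject depths against zero
    (two-sided).  Subject stage: one-sample t test of that subject's
    per-presentation deviations (predicted - observed) against zero.
    """

    t: float
    df: int
    p: float
    mean_depth: float
    degenerate: bool
    subject_t: np.ndarray = field(repr=False)
    subject_p: np.ndarray = field(repr=False)
    n_significant: int = 0
    alpha: float = 0.05


# ---------------------------------------------------------------------------
# core fits
# ---------------------------------------------------------------------------

def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares line y = intercept + slope*x; raises on zero x-variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.ptp(x) == 0.0:
        raise SingularFitError("need >= 2 distinct humanlikeness values for a linear fit")
    xm = x.mean()
    ym = y.mean()
    dx = x - xm
    slope = float(dx @ (y - ym) / (dx @ dx))
    intercept = float(ym - slope * xm)
    return slope, intercept


def uv_depth_arrays(humanlikeness, outcome, target_mask,
                    target_category: str = "target") -> UVResult:
    """UV depth from aligned arrays of per-stimulus means.

    Parameters
    ----------
    humanlikeness, outcome : array-like
        Per-stimulus mean humanlikeness and outcome (likability or neural
        amplitude), one entry per stimulus (or per category for patterns).
    target_mask : boolean array-like
        True for stimuli belonging to the UV target set; these are excluded
        from the linear fit and define the observed mean.
    """
    h = np.asarray(humanlikeness, dtype=float)
    y = np.asarray(outcome, dtype=float)
    m = np.asarray(target_mask, dtype=bool)
    if not m.any():
        raise ValueError("target mask selects no stimuli")
    slope, intercept = _ols_line(h[~m], y[~m])
    predicted = intercept + slope * float(h[m].mean())
    observed = float(y[m].mean())
    return UVResult(slope=slope, intercept=intercept, predicted=predicted,
                    observed=observed, uv_depth=predicted - observed,
                    target_category=target_category, n_points=int((~m).sum()))


def stimulus_means(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-stimulus mean ratings from a tidy trial table.

    Expects columns ``stimulus``, ``category`` and the three rating scales;
    returns one row per stimulus.
    """
    cols = [c for c in ("likability", "familiarity", "humanlikeness")
            if c in trials.columns]
    g = (trials.groupby(["stimulus", "category"], sort=False, observed=True)[cols]
         .mean().reset_index())
    return g


def uv_depth(stim_means: pd.DataFrame, target_category: str = "artificial_human",
             include_androids: bool = False,
             outcome: str = "likability") -> UVResult:
    """Linear-continuum UV depth for one subject.

    ``stim_means`` is the output of :func:`stimulus_means` (per-stimulus
    subject-mean ratings).  The fit uses all stimuli outside the target
    set; with ``include_androids`` the android category joins the target
    set (a robustness option mirroring the observation that the UV effect
    survives this redefinition).
    """
    targets = {target_category}
    if include_androids:
        targets.add("android")
    mask = stim_means["category"].isin(targets).to_numpy()
    return uv_depth_arrays(stim_means["humanlikeness"].to_numpy(),
                           stim_means[outcome].to_numpy(),
                           mask, target_category=target_category)


def uv_depth_residuals(stim_means: pd.DataFrame,
                       outcome: str = "likability") -> ResidualProfile:
    """Leave-one-category-out residual profile.

    For each of the six categories, fit likability on humanlikeness over
    the other five categories' stimuli, predict the left-out category and
    record mean(observed - predicted).  The prediction for a category never
    uses that category's data.
    """
    cats = list(dict.fromkeys(stim_means["category"]))
    h = stim_means["humanlikeness"].to_numpy(dtype=float)
    y = stim_means[outcome].to_numpy(dtype=float)
    cat_arr = stim_means["category"].to_numpy()
    residuals = np.empty(len(cats))
    fits = []
    for i, c in enumerate(cats):
        m = cat_arr == c
        slope, intercept = _ols_line(h[~m], y[~m])
        pred = intercept + slope * h[m]
        residuals[i] = float(np.mean(y[m] - pred))
        fits.append((slope, intercept))
    return ResidualProfile(categories=tuple(cats), residuals=residuals,
                           fits=tuple(fits))


def cubic_uv_fit(humanlikeness, outcome) -> CubicFit:
    """Least-squares cubic of the outcome on humanlikeness.

    ``r_squared = 1 - SSE/SST`` on the fitted data; a constant outcome
    (SST = 0) is reported as ``r_squared = 0`` with the degenerate flag.
    """
    x = np.asarray(humanlikeness, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if np.unique(x).size < 4:
        raise SingularFitError("cubic fit needs >= 4 distinct humanlikeness values")
    design = np.vander(x, 4, increasing=True)
    if np.linalg.matrix_rank(design) < 4:
        raise SingularFitError("rank-deficient cubic design")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return CubicFit(coefficients=coef, r_squared=0.0, degenerate=True)
    return CubicFit(coefficients=coef, r_squared=1.0 - sse / sst)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def presentation_deviations(trials: pd.DataFrame, fit: UVResult,
                            target_category: str = "artificial_human",
                            outcome: str = "likability") -> np.ndarray:
    """Per-presentation deviations (predicted - observed) for the target.

    The prediction is evaluated at each target stimulus's mean rated
    humanlikeness (a stable x), and compared against each individual
    presentation's rating, giving one deviation per presentation — the
    observation unit for the within-subject significance test.
    """
    t = trials[trials["category"] == target_category]
    if t.empty:
        raise ValueError(f"no trials for target category {target_category!r}")
    mean_h = t.groupby("stimulus", observed=True)["humanlikeness"].transform("mean")
    predicted = fit.intercept + fit.slope * mean_h.to_numpy(dtype=float)
    return predicted - t[outcome].to_numpy(dtype=float)


def group_uv_tests(depths, per_trial_deviations, alpha: float = 0.05) -> GroupUVTests:
    """Random-effects UV inference.

    ``depths`` holds one UV depth per subject; ``per_trial_deviations`` one
    array of per-presentation deviations per subject.  Both tests are
    two-sided one-sample t tests against zero.  Zero variance yields the
    degenerate flag with an undefined (NaN) p.
    """
    d = np.asarray(depths, dtype=float)
    if d.size < 2:
        raise ValueError("group test needs >= 2 subjects")
    degenerate = bool(np.allclose(d, d[0]))
    if degenerate and d[0] == 0.0:
        t_stat, p = 0.0, float("nan")
    elif degenerate:
        t_stat, p = float("nan"), float("nan")
    else:
        res = stats.ttest_1samp(d, 0.0)
        t_stat, p = float(res.statistic), float(res.pvalue)

    sub_t = np.full(len(per_trial_deviations), np.nan)
    sub_p = np.full(len(per_trial_deviations), np.nan)
    for i, dev in enumerate(per_trial_deviations):
        dev = np.asarray(dev, dtype=float)
        if dev.size < 2 or np.allclose(dev, dev[0]):
            continue
        res = stats.ttest_1samp(dev, 0.0)
        sub_t[i], sub_p[i] = res.statistic, res.pvalue
    n_sig = int(np.sum(sub_p < alpha))
    return GroupUVTests(t=t_stat, df=d.size - 1, p=p, mean_depth=float(d.mean()),
                        degenerate=degenerate, subject_t=sub_t, subject_p=sub_p,
                        n_significant=n_sig, alpha=alpha)
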