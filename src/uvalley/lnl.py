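"""Linear-nonlinear (LNL) region response models.

Four regions carry distinct humanlikeness codes, modelled on category-mean
activity patterns over the six stimulus categories:

* **TPJ** — linear humanlikeness: ``a + b*h``.
* **FFG** — inverse linear humanlikeness selectively for nonhumans
  (``d - e*h``, with ``e >= 0``) and an undifferentiated constant ``c``
  for human stimuli.
* **DMPFC** — human-detection step: ``baseline + step*1[human]`` with an
  optional nonhuman humanlikeness slope (off by default).
* **VMPFC** — multiplicative combination of the TPJ and FFG signals behind
  an affine wrapper: ``m + k * TPJ * FFG``.  The product of an increasing
  and a decreasing linear term is concave over the nonhuman range, so the
  most humanlike nonhuman category (artificial humans) falls below the
  linear continuum — the neural uncanny valley.

Fitting is plain least squares per region; the VMPFC reconstruction
regresses a measured pattern on the product of measured TPJ and FFG
patterns, which is the quantitative form of "multiplicative combination
of measured signals approximates the measured valuation pattern".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .uvquant import SingularFitError, UVResult, uv_depth_arrays

__all__ = [
    "TPJParams", "FFGParams", "DMPFCParams", "VMPFCParams", "LNLParams",
    "RegionPattern", "REGIONS",
    "lnl_predict", "fit_lnl", "reconstruct_vmpfc", "neural_uv_depth",
]

REGIONS = ("TPJ", "FFG", "DMPFC", "VMPFC")


@dataclass(frozen=True)
class TPJParams:
    intercept: float = 1.5
    slope: float = 0.5


@dataclass(frozen=True)
class FFGParams:
    nonhuman_intercept: float = 3.6
    nonhuman_slope: float = 1.0      # magnitude of the negative slope; >= 0
    human_level: float = 1.6

    def __post_init__(self):
        if self.nonhuman_slope < 0:
            raise ValueError("FFG nonhuman slope magnitude must be >= 0")


@dataclass(frozen=True)
class DMPFCParams:
    baseline: float = 1.0
    step: float = 1.5                # human-detection step height; >= 0
    nonhuman_slope: float = 0.0      # optional graded nonhuman component

    def __post_init__(self):
        if self.step < 0:
            raise ValueError("DMPFC step height must be >= 0")


@dataclass(frozen=True)
class VMPFCParams:
    gain: float = 1.0                # k
    offset: float = 1.6              # m


@dataclass(frozen=True)
class LNLParams:
    """Ground-truth / fitted parameters of all four region models."""

    tpj: TPJParams = field(default_factory=TPJParams)
    ffg: FFGParams = field(default_factory=FFGParams)
    dmpfc: DMPFCParams = field(default_factory=DMPFCParams)
    vmpfc: VMPFCParams = field(default_factory=VMPFCParams)

    def with_vmpfc_gain(self, k: float) -> "LNLParams":
        return replace(self, vmpfc=replace(self.vmpfc, gain=k))


@dataclass(frozen=True)
class RegionPattern:
    """Per-category mean amplitude for one region (category order fixed)."""

    region: str
    categories: tuple[str, ...]
    amplitudes: np.ndarray

    def __post_init__(self):
        if len(self.categories) != len(self.amplitudes):
            raise ValueError("pattern length mismatch")


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def lnl_predict(params: LNLParams, region: str, humanlikeness, is_human):
    """Noiseless region response to stimuli of given humanlikeness.

    Vectorised over ``humanlikeness`` / ``is_human``.  VMPFC is, by
    construction, exactly ``m + k * TPJ(h) * FFG(h, human)`` for all inputs.
    """
    h = np.asarray(humanlikeness, dtype=float)
    human = np.asarray(is_human, dtype=bool)
    if region == "TPJ":
        out = params.tpj.intercept + params.tpj.slope * h
    elif region == "FFG":
        f = params.ffg
        out = np.where(human, f.human_level, f.nonhuman_intercept - f.nonhuman_slope * h)
    elif region == "DMPFC":
        d = params.dmpfc
        out = d.baseline + d.step * human + np.where(human, 0.0, d.nonhuman_slope * h)
    elif region == "VMPFC":
        v = params.vmpfc
        out = v.offset + v.gain * (lnl_predict(params, "TPJ", h, human)
                                   * lnl_predict(params, "FFG", h, human))
    else:
        raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")
    if np.isscalar(humanlikeness) and np.isscalar(is_human):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _affine_lstsq(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(slope, intercept) of y on x by least squares; raises on degeneracy."""
    if x.size < 2 or np.ptp(x) == 0.0:
        raise SingularFitError("degenerate design for affine fit")
    design = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(coef[0]), float(coef[1])


def fit_lnl(patterns: dict[str, np.ndarray], humanlikeness, is_human,
            dmpfc_nonhuman_slope: bool = False) -> LNLParams:
    """Fit all four region models to measured category patterns.

    ``patterns`` maps region name to a 6-vector of category-mean
    amplitudes aligned with ``humanlikeness`` (category-mean rated
    humanlikeness) and ``is_human``.  TPJ: line over all categories.
    FFG: line over nonhumans, mean over humans.  DMPFC: step model
    (optionally plus a nonhuman slope).  VMPFC: (gain, offset) by
    regressing the measured pattern on the product of the measured TPJ
    and FFG patterns.
    """
    missing = [r for r in REGIONS if r not in patterns]
    if missing:
        raise ValueError(f"missing region patterns: {missing}")
    h = np.asarray(humanlikeness, dtype=float)
    human = np.asarray(is_human, dtype=bool)
    tpj_y = np.asarray(patterns["TPJ"], dtype=float)
    ffg_y = np.asarray(patterns["FFG"], dtype=float)
    dm_y = np.asarray(patterns["DMPFC"], dtype=float)
    vm_y = np.asarray(patterns["VMPFC"], dtype=float)

    b, a = _affine_lstsq(h, tpj_y)
    tpj = TPJParams(intercept=a, slope=b)

    neg_slope, d0 = _affine_lstsq(h[~human], ffg_y[~human])
    ffg = FFGParams(nonhuman_intercept=d0, nonhuman_slope=max(-neg_slope, 0.0),
                    human_level=float(ffg_y[human].mean()))

    if dmpfc_nonhuman_slope:
        slope_nh, base = _affine_lstsq(h[~human], dm_y[~human])
        dmpfc = DMPFCParams(baseline=base,
                            step=max(float(dm_y[human].mean()) - base, 0.0),
                            nonhuman_slope=slope_nh)
    else:
        base = float(dm_y[~human].mean())
        dmpfc = DMPFCParams(baseline=base,
                            step=max(float(dm_y[human].mean()) - base, 0.0))

    product = tpj_y * ffg_y
    k, m = _affine_lstsq(product, vm_y)
    return LNLParams(tpj=tpj, ffg=ffg, dmpfc=dmpfc,
                     vmpfc=VMPFCParams(gain=k, offset=m))


def reconstruct_vmpfc(tpj_pattern, ffg_pattern, vmpfc_measured,
                      compose: str = "multiplicative"):
    """Reconstruct the VMPFC valuation pattern from TPJ and FFG signals.

    computed = m + k * (TPJ x FFG) with (k, m) by least squares against the
    measured pattern; returns ``(computed, r)`` where r is the Pearson
    correlation between computed and measured.  ``compose="additive"`` is a
    descriptive alternative (m + k1*TPJ + k2*FFG) for fit-quality
    comparison.  A constant measured pattern gives r = NaN.
    """
    tpj = np.asarray(tpj_pattern, dtype=float)
    ffg = np.asarray(ffg_pattern, dtype=float)
    vm = np.asarray(vmpfc_measured, dtype=float)
    if compose == "multiplicative":
        product = tpj * ffg
        k, m = _affine_lstsq(product, vm)
        computed = m + k * product
    elif compose == "additive":
        design = np.column_stack([tpj, ffg, np.ones_like(tpj)])
        coef, *_ = np.linalg.lstsq(design, vm, rcond=None)
        computed = design @ coef
    else:
        raise ValueError("compose must be 'multiplicative' or 'additive'")
    if np.ptp(vm) == 0.0 or np.ptp(computed) == 0.0:
        return computed, float("nan")
    r = float(np.corrcoef(computed, vm)[0, 1])
    return computed, r


def neural_uv_depth(pattern, humanlikeness, is_target,
                    target_category: str = "artificial_human") -> UVResult:
    """UV depth applied to a neural category pattern.

    Identical contract to the behavioral UV depth: linear fit of amplitude
    on humanlikeness over non-target categories, depth = predicted minus
    observed amplitude of the target.
    """
    return uv_depth_arrays(humanlikeness, pattern, is_target,
                           target_category=target_category)
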