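"""Experimental design and synthetic-data generation.

The emulated experiment: 21 subjects rate 36 stimuli (6 categories x 6
exemplars) twice on likability, familiarity and humanlikeness (continuous
1-5 analog scales; 72 rating trials), and make 108 two-alternative gift
choices organised in 9 category contrasts of 12 order-balanced trials
each.  Stimulus categories span a humanlikeness continuum from mechanoid
robots to unimpaired humans, with "artificial humans" as the uncanny-valley
(UV) category.

Ground-truth generative model per subject:

* humanlikeness rating = latent category humanlikeness + Gaussian noise;
* likability = intercept + slope * latent - uv_dip * 1[artificial human]
  + noise (the dip is the injected UV; uv_dip = 0 is the null subject);
* familiarity = baseline + coupling * (centered likability signal) + noise,
  with the coupling calibrated so the population likability-familiarity
  shared variance sits near R^2 = 0.39;
* choices: P(second chosen) = logistic(b0 + b1*dLik + b2*dFam + b3*dHum)
  with deltas = first - second stimulus mean ratings (so a subject who
  prefers the more likable agent has negative b1..b3);
* confidence = monotone function of |decision variable| + noise;
* per-trial ROI amplitudes from the linear-nonlinear region models plus
  Gaussian noise; amygdala = negative gain x a value proxy;
* BOLD: amplitude-scaled canonical HRFs at jittered event onsets (ITI
  uniform on 2-6 s), TR = 2 s, optional slow drift and white noise.

All randomness flows through explicit integer seeds; identical
(config, seed) pairs give bitwise-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .choicemodel import DataConsistencyError, relative_attributes
from .lnl import (DMPFCParams, FFGParams, LNLParams, TPJParams, VMPFCParams,
                  lnl_predict)
from .roistats import HRF, events_to_series

__all__ = [
    "Category", "Stimulus", "RatingTrial", "ChoiceContrast", "ChoiceTrial",
    "SubjectParams", "PopulationConfig", "BoldSession",
    "DEFAULT_CATEGORIES", "CATEGORY_ORDER",
    "build_stimulus_set", "build_rating_trials", "build_choice_design",
    "sample_population", "simulate_ratings", "simulate_rating_values",
    "simulate_choices", "simulate_choice_values", "simulate_roi_amplitudes",
    "simulate_bold", "build_onsets", "simulate_subject",
    "ratings_frame", "choices_frame", "save_bold", "load_bold",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Category:
    name: str
    is_human: bool
    latent_humanlikeness: float

    def __post_init__(self):
        if not 1.0 <= self.latent_humanlikeness <= 5.0:
            raise ValueError("latent humanlikeness must lie in [1, 5]")


# Fixed category order along the latent humanlikeness continuum; exactly the
# two human categories carry is_human=True.  The UV-relevant artificial
# humans sit between androids and humans.
DEFAULT_CATEGORIES: tuple[Category, ...] = (
    Category("mechanoid", False, 1.6),
    Category("humanoid", False, 2.2),
    Category("android", False, 2.9),
    Category("artificial_human", False, 3.2),
    Category("human_phys_impair", True, 4.1),
    Category("human_no_impair", True, 4.5),
)
CATEGORY_ORDER: tuple[str, ...] = tuple(c.name for c in DEFAULT_CATEGORIES)
UV_CATEGORY = "artificial_human"


@dataclass(frozen=True)
class Stimulus:
    id: str
    category: Category
    exemplar_index: int


@dataclass(frozen=True)
class RatingTrial:
    stimulus: Stimulus
    repetition: int
    likability: float | None = None
    familiarity: float | None = None
    humanlikeness: float | None = None


@dataclass(frozen=True)
class ChoiceContrast:
    reference_category: Category
    other_category: Category

    @property
    def label(self) -> str:
        return f"{self.reference_category.name}_vs_{self.other_category.name}"


@dataclass(frozen=True)
class ChoiceTrial:
    contrast: ChoiceContrast
    first: Stimulus
    second: Stimulus
    choice: int | None = None        # 0 = first chosen, 1 = second chosen
    confidence: float | None = None


@dataclass(frozen=True)
class SubjectParams:
    """Ground-truth generating parameters of one simulated subject."""

    intercept_likability: float = 1.0
    slope_likability: float = 0.6
    uv_dip: float = 0.8
    rating_noise_sd: float = 0.4
    familiarity_coupling: float = 0.62
    familiarity_baseline: float = 3.0
    betas: tuple[float, float, float, float] = (0.0, -1.3, -0.55, -0.6)
    confidence_gain: float = 1.2
    confidence_noise_sd: float = 0.4
    amplitude_noise_sd: float = 0.2
    amygdala_gain: float = 0.8
    lnl: LNLParams = field(default_factory=LNLParams)

    def __post_init__(self):
        if self.uv_dip < 0:
            raise ValueError("uv_dip must be >= 0")
        for name in ("rating_noise_sd", "confidence_noise_sd", "amplitude_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.familiarity_coupling <= 1.0:
            raise ValueError("familiarity_coupling must lie in [0, 1]")


@dataclass(frozen=True)
class BoldSession:
    """One simulated session of ROI BOLD activity."""

    series: np.ndarray
    tr: float
    onsets: np.ndarray
    duration: float


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_stimulus_set(n_per_category: int = 6,
                       categories: tuple[Category, ...] = DEFAULT_CATEGORIES
                       ) -> list[Stimulus]:
    """Exemplars for every category, in fixed category order."""
    if n_per_category < 1:
        raise ValueError("n_per_category must be >= 1")
    return [Stimulus(id=f"{cat.name}_{k:02d}", category=cat, exemplar_index=k)
            for cat in categories for k in range(1, n_per_category + 1)]


def build_rating_trials(stimuli: list[Stimulus], repetitions: int = 2,
                        seed: int = 0) -> list[RatingTrial]:
    """Seeded permutation of every stimulus presented ``repetitions`` times."""
    if not stimuli:
        raise ValueError("empty stimulus list")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    trials = [RatingTrial(stimulus=s, repetition=r)
              for r in range(1, repetitions + 1) for s in stimuli]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


def build_choice_design(stimuli: list[Stimulus], trials_per_contrast: int = 12,
                        seed: int = 0
                        ) -> tuple[list[ChoiceContrast], list[ChoiceTrial]]:
    """Two-reference contrast scheme with order-balanced trials.

    Unimpaired humans are compared against every other category; androids
    against every remaining category except unimpaired humans.  Each
    contrast receives ``trials_per_contrast`` trials over unique exemplar
    pairs, half starting with each category.
    """
    if trials_per_contrast % 2 != 0:
        raise ValueError("trials_per_contrast must be even for order balance")
    by_cat: dict[str, list[Stimulus]] = {}
    cats: list[Category] = []
    for s in stimuli:
        if s.category.name not in by_cat:
            by_cat[s.category.name] = []
            cats.append(s.category)
        by_cat[s.category.name].append(s)

    contrasts: list[ChoiceContrast] = []
    for ref_name, excluded in (("human_no_impair", ()),
                               ("android", ("human_no_impair",))):
        ref = next((c for c in cats if c.name == ref_name), None)
        if ref is None:
            continue
        for other in cats:
            if other.name == ref_name or other.name in excluded:
                continue
            if any(k.reference_category.name == other.name
                   and k.other_category.name == ref_name for k in contrasts):
                continue
            contrasts.append(ChoiceContrast(reference_category=ref,
                                            other_category=other))

    rng = np.random.default_rng(seed)
    trials: list[ChoiceTrial] = []
    for con in contrasts:
        a = by_cat[con.reference_category.name]
        b = by_cat[con.other_category.name]
        n_pairs = len(a) * len(b)
        if n_pairs < trials_per_contrast:
            raise ValueError("not enough exemplar pairs for unique choice trials")
        pick = rng.choice(n_pairs, size=trials_per_contrast, replace=False)
        for t, flat in enumerate(pick):
            sa, sb = a[flat // len(b)], b[flat % len(b)]
            first, second = (sa, sb) if t < trials_per_contrast // 2 else (sb, sa)
            trials.append(ChoiceTrial(contrast=con, first=first, second=second))
    order = rng.permutation(len(trials))
    return contrasts, [trials[i] for i in order]


def build_onsets(n_events: int, seed: int = 0, start: float = 10.0,
                 slot: float = 8.0, iti_range: tuple[float, float] = (2.0, 6.0)
                 ) -> np.ndarray:
    """Event onsets: fixed stimulus slot plus jittered inter-trial interval."""
    rng = np.random.default_rng(seed)
    itis = rng.uniform(*iti_range, size=n_events - 1)
    return start + np.concatenate([[0.0], np.cumsum(slot + itis)])


# ---------------------------------------------------------------------------
# population sampling
# ---------------------------------------------------------------------------

_SCALAR_PARAMS = (
    "intercept_likability", "slope_likability", "uv_dip", "rating_noise_sd",
    "familiarity_coupling", "familiarity_baseline",
    "beta0", "beta1", "beta2", "beta3",
    "confidence_gain", "confidence_noise_sd",
    "amplitude_noise_sd", "amygdala_gain",
    "tpj_intercept", "tpj_slope",
    "ffg_intercept", "ffg_slope", "ffg_human_level",
    "dmpfc_baseline", "dmpfc_step", "dmpfc_nonhuman_slope",
    "vmpfc_gain", "vmpfc_offset",
)

_DEFAULT_MEANS = {
    "intercept_likability": 1.0, "slope_likability": 0.6, "uv_dip": 0.8,
    "rating_noise_sd": 0.4, "familiarity_coupling": 0.62,
    "familiarity_baseline": 3.0,
    "beta0": 0.0, "beta1": -1.3, "beta2": -0.55, "beta3": -0.6,
    "confidence_gain": 1.2, "confidence_noise_sd": 0.4,
    "amplitude_noise_sd": 0.2, "amygdala_gain": 0.8,
    "tpj_intercept": 1.5, "tpj_slope": 0.5,
    "ffg_intercept": 3.6, "ffg_slope": 1.0, "ffg_human_level": 1.6,
    "dmpfc_baseline": 1.0, "dmpfc_step": 1.5, "dmpfc_nonhuman_slope": 0.0,
    "vmpfc_gain": 1.0, "vmpfc_offset": 1.6,
}

_DEFAULT_SDS = {
    "intercept_likability": 0.10, "slope_likability": 0.06, "uv_dip": 0.30,
    "rating_noise_sd": 0.05, "familiarity_coupling": 0.05,
    "familiarity_baseline": 0.10,
    "beta0": 0.15, "beta1": 0.24, "beta2": 0.14, "beta3": 0.17,
    "confidence_gain": 0.15, "confidence_noise_sd": 0.05,
    "amplitude_noise_sd": 0.03, "amygdala_gain": 0.20,
    "tpj_intercept": 0.12, "tpj_slope": 0.05,
    "ffg_intercept": 0.15, "ffg_slope": 0.10, "ffg_human_level": 0.12,
    "dmpfc_baseline": 0.10, "dmpfc_step": 0.15, "dmpfc_nonhuman_slope": 0.0,
    "vmpfc_gain": 0.15, "vmpfc_offset": 0.12,
}

# parameters constrained during sampling: (low, high) clip bounds
_CLIP = {
    "uv_dip": (0.0, np.inf),
    "rating_noise_sd": (0.0, np.inf),
    "confidence_noise_sd": (0.0, np.inf),
    "amplitude_noise_sd": (0.0, np.inf),
    "familiarity_coupling": (0.0, 1.0),
    "ffg_slope": (0.0, np.inf),
    "dmpfc_step": (0.0, np.inf),
}


@dataclass
class PopulationConfig:
    """Population-level means and between-subject SDs of every generator
    parameter, plus the design sizes.

    ``neural_coupling_corr`` correlates a subject's behavioral UV dip with
    their VMPFC gain, so that behavioral and neural valley depths covary
    across subjects (as in across-subject brain-behavior analyses).
    """

    n_subjects: int = 21
    n_exemplars: int = 6
    repetitions: int = 2
    trials_per_contrast: int = 12
    neural_coupling_corr: float = 0.5
    means: dict = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    sds: dict = field(default_factory=lambda: dict(_DEFAULT_SDS))

    def __post_init__(self):
        for name in _SCALAR_PARAMS:
            if name not in self.means or name not in self.sds:
                raise ValueError(f"config missing mean/sd for {name!r}")
            if self.sds[name] < 0:
                raise ValueError(f"negative SD for {name!r}")
        if not -1.0 <= self.neural_coupling_corr <= 1.0:
            raise ValueError("neural_coupling_corr must lie in [-1, 1]")

    def null(self) -> "PopulationConfig":
        """The no-UV population: uv_dip identically zero."""
        means = dict(self.means, uv_dip=0.0)
        sds = dict(self.sds, uv_dip=0.0)
        return replace(self, means=means, sds=sds)

    # -- serialisation -----------------------------------------------------
    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationConfig":
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "PopulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _params_from_draw(draw: dict[str, float]) -> SubjectParams:
    lnl = LNLParams(
        tpj=TPJParams(draw["tpj_intercept"], draw["tpj_slope"]),
        ffg=FFGParams(draw["ffg_intercept"], draw["ffg_slope"],
                      draw["ffg_human_level"]),
        dmpfc=DMPFCParams(draw["dmpfc_baseline"], draw["dmpfc_step"],
                          draw["dmpfc_nonhuman_slope"]),
        vmpfc=VMPFCParams(draw["vmpfc_gain"], draw["vmpfc_offset"]),
    )
    return SubjectParams(
        intercept_likability=draw["intercept_likability"],
        slope_likability=draw["slope_likability"],
        uv_dip=draw["uv_dip"],
        rating_noise_sd=draw["rating_noise_sd"],
        familiarity_coupling=draw["familiarity_coupling"],
        familiarity_baseline=draw["familiarity_baseline"],
        betas=(draw["beta0"], draw["beta1"], draw["beta2"], draw["beta3"]),
        confidence_gain=draw["confidence_gain"],
        confidence_noise_sd=draw["confidence_noise_sd"],
        amplitude_noise_sd=draw["amplitude_noise_sd"],
        amygdala_gain=draw["amygdala_gain"],
        lnl=lnl,
    )


def sample_population(config: PopulationConfig, seed: int = 0
                      ) -> list[SubjectParams]:
    """Draw subject parameter sets from the population distribution.

    Independent Gaussian draws per parameter, except (uv_dip, vmpfc_gain)
    which share a bivariate-normal correlation of
    ``config.neural_coupling_corr``.  Sign/range-constrained parameters
    are clipped to their admissible set.  All SDs zero reproduces the mean
    subject exactly.
    """
    rng = np.random.default_rng(seed)
    n = config.n_subjects
    rho = config.neural_coupling_corr
    z_dip = rng.standard_normal(n)
    z_gain = rho * z_dip + np.sqrt(max(1.0 - rho ** 2, 0.0)) * rng.standard_normal(n)
    shared = {"uv_dip": z_dip, "vmpfc_gain": z_gain}
    draws = {}
    for name in _SCALAR_PARAMS:
        z = shared.get(name)
        if z is None:
            z = rng.standard_normal(n)
        vals = config.means[name] + config.sds[name] * z
        if name in _CLIP:
            vals = np.clip(vals, *_CLIP[name])
        draws[name] = vals
    return [_params_from_draw({k: float(v[i]) for k, v in draws.items()})
            for i in range(n)]


# ---------------------------------------------------------------------------
# rating simulation
# ---------------------------------------------------------------------------

def simulate_rating_values(params: SubjectParams, latent: np.ndarray,
                           is_artificial: np.ndarray, seed: int
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Core generative equations on per-trial arrays.

    Returns (humanlikeness, likability, familiarity) ratings clipped to
    the [1, 5] analog scale.  ``latent`` is the latent humanlikeness of
    each trial's stimulus; ``is_artificial`` flags the UV category.
    """
    rng = np.random.default_rng(seed)
    lat = np.asarray(latent, dtype=float)
    art = np.asarray(is_artificial, dtype=bool)
    sd = params.rating_noise_sd
    signal = (params.intercept_likability + params.slope_likability * lat
              - params.uv_dip * art)
    hum = lat + sd * rng.standard_normal(lat.size)
    lik = signal + sd * rng.standard_normal(lat.size)
    fam_sig = (params.familiarity_baseline
               + params.familiarity_coupling * (signal - signal.mean()))
    fam = fam_sig + sd * rng.standard_normal(lat.size)
    clip = lambda x: np.clip(x, 1.0, 5.0)
    return clip(hum), clip(lik), clip(fam)


def simulate_ratings(params: SubjectParams, trials: list[RatingTrial],
                     seed: int = 0) -> list[RatingTrial]:
    """Fill the three rating scales of a rating-trial list."""
    latent = np.array([t.stimulus.category.latent_humanlikeness for t in trials])
    art = np.array([t.stimulus.category.name == UV_CATEGORY for t in trials])
    hum, lik, fam = simulate_rating_values(params, latent, art, seed)
    return [replace(t, humanlikeness=float(h), likability=float(l),
                    familiarity=float(f))
            for t, h, l, f in zip(trials, hum, lik, fam)]


# ---------------------------------------------------------------------------
# choice simulation
# ---------------------------------------------------------------------------

def simulate_choice_values(params: SubjectParams, dlik, dfam, dhum, seed: int
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Choices and confidences from relative rating differences.

    P(choice = second) = logistic(b0 + b1*dLik + b2*dFam + b3*dHum) with
    deltas defined as first minus second; confidence rises monotonically
    with the magnitude of the decision variable.
    """
    rng = np.random.default_rng(seed)
    b0, b1, b2, b3 = params.betas
    dv = (b1 * np.asarray(dlik, dtype=float)
          + b2 * np.asarray(dfam, dtype=float)
          + b3 * np.asarray(dhum, dtype=float))
    p_second = 1.0 / (1.0 + np.exp(-(b0 + dv)))
    choice = (rng.random(dv.size) < p_second).astype(int)
    conf = (1.0 + params.confidence_gain * np.abs(dv)
            + params.confidence_noise_sd * rng.standard_normal(dv.size))
    return choice, np.clip(conf, 1.0, 5.0), p_second


def simulate_choices(params: SubjectParams, choice_trials: list[ChoiceTrial],
                     rating_means: pd.DataFrame, seed: int = 0
                     ) -> list[ChoiceTrial]:
    """Fill choices and confidences given the subject's stimulus ratings.

    ``rating_means`` is the per-stimulus mean rating table of the same
    subject (columns stimulus / likability / familiarity / humanlikeness,
    e.g. from :func:`uvalley.uvquant.stimulus_means`); a stimulus without
    ratings raises :class:`DataConsistencyError`.
    """
    from .choicemodel import _means_lookup
    lut = _means_lookup(rating_means)
    deltas = np.array([relative_attributes(t, lut) for t in choice_trials])
    choice, conf, _ = simulate_choice_values(params, deltas[:, 0], deltas[:, 1],
                                             deltas[:, 2], seed)
    return [replace(t, choice=int(c), confidence=float(f))
            for t, c, f in zip(choice_trials, choice, conf)]


# ---------------------------------------------------------------------------
# neural simulation
# ---------------------------------------------------------------------------

ROI_REGIONS = ("TPJ", "FFG", "DMPFC", "VMPFC", "amygdala")


def simulate_roi_amplitudes(params: SubjectParams, trials: list[RatingTrial],
                            seed: int = 0) -> dict[str, np.ndarray]:
    """Per-trial response amplitudes for the five regions.

    TPJ/FFG/DMPFC/VMPFC follow the linear-nonlinear region models driven
    by the stimulus's latent humanlikeness; the amygdala carries a
    negative-gain code of a value proxy (the centered likability signal),
    without any confidence component.
    """
    rng = np.random.default_rng(seed)
    lat = np.array([t.stimulus.category.latent_humanlikeness for t in trials])
    human = np.array([t.stimulus.category.is_human for t in trials])
    art = np.array([t.stimulus.category.name == UV_CATEGORY for t in trials])
    sd = params.amplitude_noise_sd
    out: dict[str, np.ndarray] = {}
    for region in ("TPJ", "FFG", "DMPFC", "VMPFC"):
        clean = lnl_predict(params.lnl, region, lat, human)
        out[region] = clean + sd * rng.standard_normal(lat.size)
    value = (params.intercept_likability + params.slope_likability * lat
             - params.uv_dip * art)
    proxy = value - value.mean()
    out["amygdala"] = -params.amygdala_gain * proxy + sd * rng.standard_normal(lat.size)
    return out


def simulate_bold(amplitudes, onsets, tr: float, duration: float, hrf: HRF,
                  noise_sd: float = 0.0, seed: int = 0,
                  drift_amplitude: float = 0.0, drift_period: float = 300.0
                  ) -> BoldSession:
    """Event-related BOLD series: impulses convolved with the HRF.

    ``series(t) = sum_i amplitude_i * hrf(t - onset_i)`` sampled at the
    TR, plus an optional slow cosine drift and white noise.  The noiseless
    series is exactly linear in the amplitudes.
    """
    amps = np.asarray(amplitudes, dtype=float)
    ons = np.asarray(onsets, dtype=float)
    if tr <= 0:
        raise ValueError("tr must be > 0")
    if np.any(np.diff(ons) < 0):
        raise ValueError("onsets must be sorted")
    if np.any(ons < 0) or np.any(ons >= duration):
        raise ValueError("onsets outside [0, duration)")
    n = int(round(duration / tr))
    series = events_to_series(amps, ons, tr, n, hrf)
    t = np.arange(n) * tr
    if drift_amplitude:
        series = series + drift_amplitude * np.cos(2 * np.pi * t / drift_period)
    if noise_sd:
        rng = np.random.default_rng(seed)
        series = series + noise_sd * rng.standard_normal(n)
    return BoldSession(series=series, tr=tr, onsets=ons, duration=duration)


# ---------------------------------------------------------------------------
# tidy tables and persistence
# ---------------------------------------------------------------------------

def ratings_frame(trials: list[RatingTrial], subject=None) -> pd.DataFrame:
    df = pd.DataFrame({
        "stimulus": [t.stimulus.id for t in trials],
        "category": [t.stimulus.category.name for t in trials],
        "repetition": [t.repetition for t in trials],
        "likability": [t.likability for t in trials],
        "familiarity": [t.familiarity for t in trials],
        "humanlikeness": [t.humanlikeness for t in trials],
    })
    if subject is not None:
        df.insert(0, "subject", subject)
    return df


def choices_frame(trials: list[ChoiceTrial], subject=None) -> pd.DataFrame:
    df = pd.DataFrame({
        "contrast": [t.contrast.label for t in trials],
        "first": [t.first.id for t in trials],
        "second": [t.second.id for t in trials],
        "first_category": [t.first.category.name for t in trials],
        "second_category": [t.second.category.name for t in trials],
        "choice": [t.choice for t in trials],
        "confidence": [t.confidence for t in trials],
    })
    if subject is not None:
        df.insert(0, "subject", subject)
    return df


def save_bold(session: BoldSession, csv_path, region: str = "") -> None:
    """Series as one-column CSV plus a JSON sidecar (tr, onsets, region)."""
    csv_path = Path(csv_path)
    pd.DataFrame({"signal": session.series}).to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "tr": session.tr, "duration": session.duration,
        "onsets": session.onsets.tolist(), "region": region,
    }, indent=1))


def load_bold(csv_path) -> tuple[BoldSession, str]:
    csv_path = Path(csv_path)
    series = pd.read_csv(csv_path)["signal"].to_numpy()
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    return (BoldSession(series=series, tr=meta["tr"],
                        onsets=np.asarray(meta["onsets"], dtype=float),
                        duration=meta["duration"]), meta.get("region", ""))


# ---------------------------------------------------------------------------
# whole-subject convenience
# ---------------------------------------------------------------------------

def simulate_subject(params: SubjectParams, stimuli: list[Stimulus] | None = None,
                     repetitions: int = 2, trials_per_contrast: int = 12,
                     seed: int = 0) -> dict:
    """Simulate one subject's full behavioral dataset.

    Returns a dict with the filled rating and choice trial lists, their
    tidy frames, the per-stimulus rating means used for choices and the
    per-trial ROI amplitudes.
    """
    from .uvquant import stimulus_means
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(4)]
    if stimuli is None:
        stimuli = build_stimulus_set()
    rating_trials = build_rating_trials(stimuli, repetitions, seed=seeds[0])
    contrasts, choice_trials = build_choice_design(stimuli, trials_per_contrast,
                                                   seed=seeds[0])
    rated = simulate_ratings(params, rating_trials, seed=seeds[1])
    rdf = ratings_frame(rated)
    means = stimulus_means(rdf)
    chosen = simulate_choices(params, choice_trials, means, seed=seeds[2])
    amplitudes = simulate_roi_amplitudes(params, rated, seed=seeds[3])
    return {"rating_trials": rated, "choice_trials": chosen,
            "contrasts": contrasts, "ratings": rdf,
            "choices": choices_frame(chosen), "rating_means": means,
            "amplitudes": amplitudes}
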