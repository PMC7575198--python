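"""Synthetic study data for the closed-loop pain-control pipeline.

Every input the analysis stages consume can be generated here with known
ground truth: yoked high/low trial sequences, two-class multivoxel response
patterns with a small informative subset, hierarchically calibrated decoder
emissions P(pain), trial-by-trial pain ratings driven by frequency-learning
surprisal, and continuous 0-10 rating traces for the thermal temporal
contrast enhancement test.  Defaults reproduce the study conditions:
19 subjects, 6 sessions of 30 trials, decoder emissions whose across-subject
class means match the reported 95% confidence intervals, and 28 subjects per
group with 5 thermal trials per test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import frequency
from ._utils import as_rng, check_probability

__all__ = [
    "TrialSequence",
    "VoxelTrialDataset",
    "EmissionModel",
    "SubjectEmissions",
    "RatingGenParams",
    "ContrastGenParams",
    "generate_trial_sequences",
    "generate_voxel_trials",
    "sample_emissions",
    "generate_ratings",
    "generate_contrast_traces",
    "calibrate_intensities",
    "calibrated_emission_model",
]

LABELS = ("high", "low")


# ---------------------------------------------------------------------------
# trial sequences
# ---------------------------------------------------------------------------

@dataclass
class TrialSequence:
    """Ordered per-session stimulus labels for one subject.

    ``sessions`` is a list of sessions, each an ordered list of labels in
    {"high", "low"}.  ``yoked_from`` records the source subject when the
    sequence is a verbatim copy of another participant's delivered sequence.
    """

    subject_id: str
    sessions: list
    yoked_from: str | None = None

    def __post_init__(self):
        lengths = {len(s) for s in self.sessions}
        if len(lengths) > 1:
            raise ValueError("all sessions within a subject must have equal length")
        for sess in self.sessions:
            for lab in sess:
                if lab not in LABELS:
                    raise ValueError(f"stimulus label must be 'high' or 'low', got {lab!r}")

    @property
    def n_sessions(self) -> int:
        return len(self.sessions)

    @property
    def n_trials_per_session(self) -> int:
        return len(self.sessions[0]) if self.sessions else 0

    def flat_labels(self) -> list:
        return [lab for sess in self.sessions for lab in sess]

    def as_binary(self) -> np.ndarray:
        """Flattened identity codes, 1 = high, 0 = low."""
        return np.asarray([1 if lab == "high" else 0 for lab in self.flat_labels()])

    def high_fraction(self) -> float:
        u = self.as_binary()
        return float(u.mean()) if u.size else float("nan")


def generate_trial_sequences(
    n_subjects: int = 19,
    n_sessions: int = 6,
    n_trials: int = 30,
    p_high: float = 0.5,
    seed=None,
    yoke: Mapping[str, str] | None = None,
) -> dict[str, TrialSequence]:
    """I.i.d. Bernoulli(p_high) sequences, with optional explicit yoking.

    ``yoke`` maps target subject id -> source subject id; the target copies
    the source's sequence element-wise (sources must not themselves be yoked
    targets).  Subject ids are "sub-01", "sub-02", ...
    """
    check_probability(p_high, "p_high")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = as_rng(seed)
    yoke = dict(yoke or {})
    ids = [f"sub-{i + 1:02d}" for i in range(n_subjects)]
    known = set(ids)
    for tgt, src in yoke.items():
        if src not in known:
            raise ValueError(f"yoke source {src!r} is not a known subject")
        if tgt not in known:
            raise ValueError(f"yoke target {tgt!r} is not a known subject")
    out: dict[str, TrialSequence] = {}
    for sid in ids:
        if sid in yoke:
            continue
        draws = rng.random((n_sessions, n_trials)) < p_high
        sessions = [["high" if d else "low" for d in row] for row in draws]
        out[sid] = TrialSequence(sid, sessions)
    for tgt, src in yoke.items():
        if src in yoke:
            raise ValueError(f"yoke source {src!r} is itself yoked; chains are not allowed")
        out[tgt] = TrialSequence(tgt, [list(s) for s in out[src].sessions], yoked_from=src)
    return {sid: out[sid] for sid in ids}


# ---------------------------------------------------------------------------
# voxel patterns
# ---------------------------------------------------------------------------

@dataclass
class VoxelTrialDataset:
    """Per-trial TR x voxel response blocks plus per-session baseline blocks.

    ``baseline`` has shape (n_sessions, n_baseline_tr, n_voxels); ``trials``
    has shape (n_trials, n_trial_tr, n_voxels).  ``ground_truth`` records the
    informative voxel index set, the class mean shift (BOLD-like arbitrary
    units) and the noise SD used for generation.
    """

    baseline: np.ndarray
    trials: np.ndarray
    labels: np.ndarray
    session_id: np.ndarray
    ground_truth: dict

    def __post_init__(self):
        if self.trials.shape[0] != len(self.labels):
            raise ValueError("trial count must equal label count")
        if self.trials.shape[2] != self.baseline.shape[2]:
            raise ValueError("baseline and trials must share the voxel dimension")

    @property
    def n_voxels(self) -> int:
        return self.trials.shape[2]


def generate_voxel_trials(
    n_trials: int = 180,
    n_voxels: int = 200,
    n_informative: int = 20,
    class_shift: float = 1.0,
    noise_sd: float = 1.0,
    n_sessions: int = 6,
    n_baseline_tr: int = 5,
    n_trial_tr: int = 5,
    trial_window: Sequence[int] = (2, 3, 4),
    seed=None,
) -> VoxelTrialDataset:
    """Two-class voxel patterns with a small informative subset.

    Baseline TRs and all non-informative voxel x TR cells are pure
    N(0, noise_sd) noise.  Within the trial window (default TRs 3-5,
    0-based indices 2-4, mimicking the BOLD response peak) informative
    voxels are shifted by +class_shift/2 on high trials and -class_shift/2
    on low trials.  Labels are balanced and shuffled within the run.
    """
    if n_informative > n_voxels:
        raise ValueError(f"n_informative ({n_informative}) exceeds n_voxels ({n_voxels})")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = as_rng(seed)
    baseline = rng.normal(0.0, noise_sd, size=(n_sessions, n_baseline_tr, n_voxels))
    trials = rng.normal(0.0, noise_sd, size=(n_trials, n_trial_tr, n_voxels))
    labels = np.array(["high", "low"] * (n_trials // 2) + ["high"] * (n_trials % 2))
    rng.shuffle(labels)
    informative = np.sort(rng.choice(n_voxels, size=n_informative, replace=False))
    signs = np.where(labels == "high", 0.5, -0.5) * class_shift
    for tr in trial_window:
        trials[:, tr, informative] += signs[:, None]
    session_id = np.repeat(np.arange(n_sessions), int(np.ceil(n_trials / n_sessions)))[:n_trials]
    return VoxelTrialDataset(
        baseline=baseline,
        trials=trials,
        labels=labels,
        session_id=session_id,
        ground_truth={
            "informative": informative,
            "class_shift": float(class_shift),
            "noise_sd": float(noise_sd),
        },
    )


# ---------------------------------------------------------------------------
# decoder emissions
# ---------------------------------------------------------------------------

# Across-subject 95% CIs of the mean decoded P(pain) per delivered class
# (n = 19): high [0.545, 0.660], low [0.410, 0.524].  Population means are
# the CI midpoints; between-subject SDs are back-solved assuming normality,
# SD = halfwidth * sqrt(n) / 1.96.
_CI_HIGH = (0.545, 0.660)
_CI_LOW = (0.410, 0.524)
_CAL_N = 19


@dataclass
class EmissionModel:
    """Hierarchical generative model of real-time decoder outputs P(pain).

    Subject-level class means are drawn once per subject from truncated
    normals on (0, 1); trial-level emissions are Beta-distributed around the
    subject mean with dispersion ``within_subject_sd``.  ``mode`` selects
    the study arm: "calibrated" (real decoder), "sham" (random feedback:
    both classes share one mean), or "perfect" (emits exactly 1 for high
    and 0 for low).

    The Beta family for trial-level emissions is a modelling choice; the
    dispersion knob is exposed because trial-level spread is not constrained
    by the across-subject summaries the defaults are calibrated to.
    """

    population_mean_high: float = 0.6025
    population_mean_low: float = 0.4670
    between_subject_sd_high: float = 0.1277
    between_subject_sd_low: float = 0.1266
    within_subject_sd: float = 0.15
    mode: str = "calibrated"

    def __post_init__(self):
        if self.mode not in ("calibrated", "sham", "perfect"):
            raise ValueError(f"unknown mode {self.mode!r}")
        check_probability(self.population_mean_high, "population_mean_high")
        check_probability(self.population_mean_low, "population_mean_low")
        if self.mode == "sham" and self.population_mean_high != self.population_mean_low:
            # sham feedback carries no class information by construction
            m = 0.5 * (self.population_mean_high + self.population_mean_low)
            self.population_mean_high = self.population_mean_low = m

    def sham(self) -> "EmissionModel":
        m = 0.5 * (self.population_mean_high + self.population_mean_low)
        return replace(self, population_mean_high=m, population_mean_low=m, mode="sham")


def calibrated_emission_model(within_subject_sd: float = 0.15) -> EmissionModel:
    """Emission model calibrated to the printed per-class P(pain) CIs."""
    def back_solve(ci):
        lo, hi = ci
        return 0.5 * (lo + hi), 0.5 * (hi - lo) * np.sqrt(_CAL_N) / 1.96

    mh, sh = back_solve(_CI_HIGH)
    ml, sl = back_solve(_CI_LOW)
    return EmissionModel(
        population_mean_high=mh,
        population_mean_low=ml,
        between_subject_sd_high=sh,
        between_subject_sd_low=sl,
        within_subject_sd=within_subject_sd,
        mode="calibrated",
    )


def _truncnorm_01(mean: float, sd: float, rng: np.random.Generator) -> float:
    if sd == 0:
        return float(np.clip(mean, 1e-6, 1 - 1e-6))
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    var = sd * sd
    vmax = mean * (1.0 - mean)
    if var >= vmax:
        warnings.warn(
            f"within-subject SD {sd:.3f} incompatible with a Beta at mean {mean:.3f}; "
            "clamping variance to 0.95 * m(1-m)",
            RuntimeWarning,
        )
        var = 0.95 * vmax
    nu = vmax / var - 1.0
    return mean * nu, (1.0 - mean) * nu


class SubjectEmissions:
    """Per-subject emission sampler with class means drawn once.

    Used both by the open-loop :func:`sample_emissions` log generator and by
    the closed-loop controller, which needs to draw an emission conditioned
    on each delivered label as the loop runs.
    """

    def __init__(self, model: EmissionModel, rng: np.random.Generator):
        self.model = model
        if model.mode == "perfect":
            self.mean_high, self.mean_low = 1.0, 0.0
        else:
            self.mean_high = _truncnorm_01(model.population_mean_high, model.between_subject_sd_high, rng)
            if model.mode == "sham":
                self.mean_low = self.mean_high
            else:
                self.mean_low = _truncnorm_01(model.population_mean_low, model.between_subject_sd_low, rng)

    def draw(self, label: str, rng: np.random.Generator) -> float:
        if label not in LABELS:
            raise ValueError(f"label must be 'high' or 'low', got {label!r}")
        if self.model.mode == "perfect":
            return 1.0 if label == "high" else 0.0
        mean = self.mean_high if label == "high" else self.mean_low
        a, b = _beta_params(mean, self.model.within_subject_sd)
        # extreme shape parameters can round to the closed endpoints
        return float(np.clip(rng.beta(a, b), 1e-9, 1.0 - 1e-9))


def sample_emissions(
    sequences: Mapping[str, TrialSequence] | TrialSequence,
    model: EmissionModel,
    seed=None,
) -> pd.DataFrame:
    """Open-loop per-trial P(pain) log for the given delivered sequences.

    Returns a long-format frame (subject, session, trial, label, p_pain).
    """
    rng = as_rng(seed)
    if isinstance(sequences, TrialSequence):
        sequences = {sequences.subject_id: sequences}
    rows = []
    for sid, seq in sequences.items():
        sampler = SubjectEmissions(model, rng)
        for s_idx, session in enumerate(seq.sessions):
            for t_idx, label in enumerate(session):
                rows.append(
                    {
                        "subject": sid,
                        "session": s_idx,
                        "trial": t_idx,
                        "label": label,
                        "p_pain": sampler.draw(label, rng),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ratings
# ---------------------------------------------------------------------------

@dataclass
class RatingGenParams:
    """Generative parameters for surprisal-coupled trial ratings.

    rating_t = beta0 + stimulus_effect * identity_t + session_drift * session_t
               + beta1 * surprisal_t(omega) + N(0, noise_sd), clipped to [0, 10].

    ``omega`` is the leaky memory factor of the generating observer
    (None = perfect memory); ``beta1`` couples the rating to the bits of
    surprisal of each delivered stimulus.
    """

    beta0: float = 5.0
    beta1: float = 0.8
    omega: float | None = 10.0
    noise_sd: float = 0.5
    stimulus_effect: float = 1.5
    session_drift: float = 0.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.omega is not None and self.omega <= 0:
            raise ValueError("omega must be positive or None")


def generate_ratings(
    sequence: TrialSequence,
    params: RatingGenParams,
    seed=None,
) -> pd.DataFrame:
    """Trial ratings generated from the frequency-learning linear model.

    Surprisal is computed by :func:`painloop.frequency.build_predictors`
    with per-session prior reset, so the generator is the exact generative
    twin of the analysis-side regression.
    Returns (subject, session, trial, label, rating).
    """
    rng = as_rng(seed)
    pred = frequency.build_predictors(sequence, omega=params.omega)
    noise = rng.normal(0.0, params.noise_sd, size=len(pred)) if params.noise_sd > 0 else 0.0
    rating = (
        params.beta0
        + params.stimulus_effect * pred["identity"].to_numpy()
        + params.session_drift * pred["session"].to_numpy()
        + params.beta1 * pred["surprisal"].to_numpy()
        + noise
    )
    out = pred[["session", "trial"]].copy()
    out.insert(0, "subject", sequence.subject_id)
    out["label"] = ["high" if i == 1 else "low" for i in pred["identity"]]
    out["rating"] = np.clip(rating, 0.0, 10.0)
    return out


# ---------------------------------------------------------------------------
# thermal contrast traces
# ---------------------------------------------------------------------------

@dataclass
class ContrastGenParams:
    """Generator settings for 45-46-45 degree C continuous rating traces.

    The deterministic base trace is a piecewise-linear plateau profile on a
    1 s grid over 21 s (phases T1/T2/T3, 7 s each).  Onset overshoot (early
    T2 bump) and offset undershoot (early T3 dip) components are scaled by
    per-group, per-condition modulation gains; the experimental group's
    post-task gain exceeds its pre-task gain, the control group's gains are
    equal.  Endogenous modulation strength varies substantially between
    people, so each subject x condition adds Gaussian jitter
    (``gain_subject_sd``) to its group gain; the default scale makes the
    between-subject spread of post - pre magnitude changes comparable to
    the group SDs observed in pre/post offset-analgesia testing.
    """

    n_subjects: int = 28
    n_trials: int = 5
    base_low: float = 4.0
    base_high: float = 5.5
    overshoot_amp: float = 1.2
    undershoot_amp: float = 1.2
    gain_pre_experimental: float = 1.0
    gain_post_experimental: float = 1.6
    gain_pre_control: float = 1.0
    gain_post_control: float = 1.0
    gain_subject_sd: float = 0.4
    trace_noise_sd: float = 0.3

    @property
    def time_grid(self) -> np.ndarray:
        return np.arange(21.0)


def phase_of(time_s) -> np.ndarray:
    """Thermal phase label for times within the 21 s stimulus train."""
    t = np.asarray(time_s, dtype=float)
    return np.select([t < 7.0, t < 14.0], ["T1", "T2"], default="T3")


def _base_components(params: ContrastGenParams):
    t = params.time_grid
    base = np.where((t >= 7.0) & (t < 14.0), params.base_high, params.base_low)
    # triangular overshoot peaking 1 s into T2, triangular undershoot 1 s into T3
    over = params.overshoot_amp * np.clip(1.0 - np.abs(t - 8.0) / 2.0, 0.0, None)
    under = -params.undershoot_amp * np.clip(1.0 - np.abs(t - 15.0) / 2.0, 0.0, None)
    return base, over + under


def generate_contrast_traces(params: ContrastGenParams, seed=None) -> pd.DataFrame:
    """Long-format rating traces: group x pre/post x subject x trial x time.

    Columns: subject, group, condition, trial, time_s, rating, phase.
    Ratings are the base trace plus gain-scaled modulation plus i.i.d.
    noise, clipped to [0, 10].
    """
    rng = as_rng(seed)
    base, modulation = _base_components(params)
    t = params.time_grid
    phases = phase_of(t)
    gains = {
        ("experimental", "pre"): params.gain_pre_experimental,
        ("experimental", "post"): params.gain_post_experimental,
        ("control", "pre"): params.gain_pre_control,
        ("control", "post"): params.gain_post_control,
    }
    rows = []
    for group in ("experimental", "control"):
        for i in range(params.n_subjects):
            sid = f"{group[:3]}-{i + 1:02d}"
            for condition in ("pre", "post"):
                g = gains[(group, condition)]
                if params.gain_subject_sd > 0:
                    g = g + rng.normal(0.0, params.gain_subject_sd)
                for trial in range(params.n_trials):
                    noise = (
                        rng.normal(0.0, params.trace_noise_sd, size=t.size)
                        if params.trace_noise_sd > 0
                        else 0.0
                    )
                    rating = np.clip(base + g * modulation + noise, 0.0, 10.0)
                    rows.append(
                        pd.DataFrame(
                            {
                                "subject": sid,
                                "group": group,
                                "condition": condition,
                                "trial": trial,
                                "time_s": t,
                                "rating": rating,
                                "phase": phases,
                            }
                        )
                    )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# psychometric intensity calibration
# ---------------------------------------------------------------------------

def _logistic10(c, c50, s):
    return 10.0 / (1.0 + np.exp(-(c - c50) / s))


def _weibull10(c, scale, shape):
    return 10.0 * (1.0 - np.exp(-((c / scale) ** shape)))


def calibrate_intensities(
    currents: Sequence[float],
    ratings: Sequence[float],
) -> tuple[float, float]:
    """Stimulator currents producing VAS 1 and VAS 8 from a rating series.

    Fits both a 2-parameter logistic psychometric curve
    ``rating(c) = 10 / (1 + exp(-(c - c50)/s))`` and a Weibull CDF scaled to
    10 by least squares, then inverts whichever fits better (lower SSE) at
    ratings 1 and 8 — the low/high pain levels used for the main task.
    """
    c = np.asarray(currents, dtype=float)
    r = np.asarray(ratings, dtype=float)
    if c.size < 4:
        raise ValueError("need at least 4 (current, rating) pairs")
    if (c <= 0).any():
        raise ValueError("currents must be positive")
    if np.ptp(r) == 0:
        raise ValueError("ratings are constant; no monotone psychometric fit exists")

    fits = []
    p0_log = (float(np.median(c)), max(float(np.ptp(c)) / 4.0, 1e-3))
    try:
        popt, _ = optimize.curve_fit(_logistic10, c, r, p0=p0_log, maxfev=10000)
        sse = float(np.sum((r - _logistic10(c, *popt)) ** 2))
        fits.append(("logistic", popt, sse))
    except RuntimeError:
        pass
    p0_wei = (float(np.median(c)), 2.0)
    try:
        popt, _ = optimize.curve_fit(
            _weibull10, c, r, p0=p0_wei, bounds=([1e-9, 1e-9], [np.inf, np.inf]), maxfev=10000
        )
        sse = float(np.sum((r - _weibull10(c, *popt)) ** 2))
        fits.append(("weibull", popt, sse))
    except RuntimeError:
        pass
    if not fits:
        raise ValueError("neither psychometric curve could be fitted")
    name, popt, _ = min(fits, key=lambda f: f[2])
    if name == "logistic":
        c50, s = popt
        if s <= 0:
            raise ValueError(f"non-monotone logistic fit (slope s = {s:.4g} <= 0)")
        invert = lambda v: c50 + s * np.log(v / (10.0 - v))
    else:
        scale, shape = popt
        if scale <= 0 or shape <= 0:
            raise ValueError(f"non-monotone Weibull fit (scale={scale:.4g}, shape={shape:.4g})")
        invert = lambda v: scale * (-np.log(1.0 - v / 10.0)) ** (1.0 / shape)
    lo, hi = float(invert(1.0)), float(invert(8.0))
    if not (np.isfinite(lo) and np.isfinite(hi)) or lo <= 0 or hi <= lo:
        raise ValueError(
            f"VAS targets fall outside the fitted range (c(VAS1)={lo:.4g}, c(VAS8)={hi:.4g})"
        )
    return lo, hi
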