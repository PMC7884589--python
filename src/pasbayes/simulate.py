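"""Synthetic trial-level MEP datasets with known ground-truth effect sizes.

The generator emulates the statistical structure the analysis pipeline
assumes:

* log-normal trial-level MEP amplitudes whose log-mean follows a saturating
  sigmoid of stimulation intensity (recruitment), anchored so the population
  geometric mean is ~0.04 mV at 90% rMT and ~0.06 mV at 100% rMT (just above
  threshold, where MEPs of ~50 uV define the motor threshold);
* participant- and session-level random intercepts on the log scale, sized so
  the between-session reliability (ICC(3)) of the pre-intervention AURC is
  modest (~0.34), as observed for week-separated TMS sessions;
* post-intervention effects injected multiplicatively on amplitudes
  (additively on log-amplitudes, uniform across intensities), with the shift
  solved in closed form so the population AURC effect size at each timepoint
  equals the requested Cohen's d;
* occasional trials with elevated background EMG (> 2.5 uV) to exercise the
  absolute rejection rule, and a log-normal background for clean trials whose
  tail exercises the whisker rule;
* optional post-hoc deletion of whole AURC cells (implemented by pushing all
  trials of one intensity above the background threshold, so the minimum
  cell-count rule fires) to exercise imputation.

One seed governs the whole table through counter-based substreams per
participant, so adding participants does not perturb existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .recruitment import INTENSITIES

CONDITIONS = ("TMS-TMS", "tACS-TMS", "Sham")
TIMEPOINTS = ("Pre", "Post0", "Post10", "Post20", "Post30")

#: Default true AURC effect sizes per condition and post timepoint (Cohen's d,
#: pre-intervention standardiser).  Active conditions follow the informed-
#: prior point estimates; sham has no effect.
DEFAULT_D_TRUE = {
    "TMS-TMS": {"Post0": 0.601, "Post10": 0.684, "Post20": 0.766, "Post30": 0.849},
    "tACS-TMS": {"Post0": 0.601, "Post10": 0.684, "Post20": 0.766, "Post30": 0.849},
    "Sham": {"Post0": 0.0, "Post10": 0.0, "Post20": 0.0, "Post30": 0.0},
}

# Recruitment sigmoid on the log-amplitude scale (mV):
# mu(x) = LO + (HI - LO) * logistic((x - X0) / W)
_SIGMOID_LO = math.log(0.03)
_SIGMOID_HI = math.log(2.2)
_SIGMOID_X0 = 124.0
_SIGMOID_W = 14.0

#: log-amplitude offset of the control muscle (ECR) relative to FCR.
_ECR_OFFSET = -0.5

#: clean-trial background RMS: truncation point and contaminated range (uV).
_RMS_CLEAN_MAX = 2.45
_RMS_CONTAMINATED_RANGE = (2.6, 8.0)


def recruitment_log_mean(intensity) -> np.ndarray:
    """Population log-mean MEP amplitude (log mV) at an intensity (%rMT)."""
    x = np.asarray(intensity, dtype=float)
    z = (x - _SIGMOID_X0) / _SIGMOID_W
    return _SIGMOID_LO + (_SIGMOID_HI - _SIGMOID_LO) / (1.0 + np.exp(-z))


@dataclass
class SimConfig:
    """Configuration of the synthetic dataset generator.

    Attributes
    ----------
    seed : int
        Master seed; identical seed + config gives a bit-identical table.
    n_participants : int
        Number of participants (default 14, the study's sample size).
    conditions, timepoints, intensities : sequences
        Design labels; ``Pre`` must be among the timepoints.
    trials_per_intensity : int
        Stimuli per intensity level (default 6).
    extra_trials_120 : int
        Additional stimuli delivered at 120% rMT (default 12, pooled with the
        curve sequence downstream).
    d_true : mapping condition -> timepoint -> Cohen's d
        Target population AURC effect size for each post-intervention
        contrast (pre-intervention standardiser).
    sigma_log : float
        Trial-level SD of log amplitude (dimensionless; default 0.6, typical
        of single-trial MEP variability).
    tau_participant, tau_session, tau_timepoint : float
        SDs of the participant-, session- and measurement-block-level
        log-amplitude intercepts.  The timepoint component models the drift
        of corticospinal state between measurement blocks within a session
        (it is what gives paired pre/post differences realistic variance);
        the participant:session ratio sets the between-session ICC of the
        pre AURC.  Defaults are tuned so the median ICC(3) is ~0.34.
    rms_base_range : (float, float)
        Range of per-participant median background RMS (uV).
    rms_session_sd, rms_trial_sd : float
        Log-scale SDs of the session-level and trial-level background-RMS
        variation.  Session-level variation makes whisker-rule rejections
        cluster within sessions, as they do in real recordings.
    contamination_rate : float
        Marginal probability that a trial has elevated (> 2.5 uV) background
        EMG.
    contamination_clustering : float
        Intra-block correlation of contamination in [0, 1): each
        (participant, condition, timepoint) block draws a contamination
        propensity from a Beta distribution with mean ``contamination_rate``
        and variance ``clustering * rate * (1 - rate)``; 0 gives independent
        per-trial contamination.  Elevated background EMG is a state of the
        participant, so real contamination arrives in session-long runs -
        which is what lets a session lose many trials while most analysis
        cells keep their five-trial minimum.
    missing_rate : float
        Probability a (participant, condition, timepoint) AURC cell is
        deleted post-hoc (via an unfillable intensity cell).
    """

    seed: int = 0
    n_participants: int = 14
    conditions: tuple = CONDITIONS
    timepoints: tuple = TIMEPOINTS
    intensities: tuple = INTENSITIES
    trials_per_intensity: int = 6
    extra_trials_120: int = 12
    d_true: dict = field(default_factory=lambda: {c: dict(d) for c, d in
                                                  DEFAULT_D_TRUE.items()})
    sigma_log: float = 0.6
    tau_participant: float = 0.27
    tau_session: float = 0.16
    tau_timepoint: float = 0.28
    rms_base_range: tuple = (0.8, 1.5)
    rms_session_sd: float = 0.30
    rms_trial_sd: float = 0.10
    contamination_rate: float = 0.03
    contamination_clustering: float = 0.85
    missing_rate: float = 0.0

    def __post_init__(self):
        for name in ("contamination_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"SimConfig.{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.contamination_clustering < 1.0:
            raise ConfigurationError(
                "SimConfig.contamination_clustering must be in [0, 1)")
        for name in ("n_participants", "trials_per_intensity"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"SimConfig.{name} must be positive")
        if self.extra_trials_120 < 0:
            raise ConfigurationError("SimConfig.extra_trials_120 must be >= 0")
        for name in ("sigma_log", "tau_participant", "tau_session",
                     "tau_timepoint"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"SimConfig.{name} must be >= 0")
        if "Pre" not in self.timepoints:
            raise ConfigurationError("SimConfig.timepoints must include 'Pre'")
        if list(self.intensities) != sorted(set(self.intensities)):
            raise ConfigurationError(
                "SimConfig.intensities must be strictly increasing")
        for c in self.conditions:
            if c not in self.d_true:
                raise ConfigurationError(f"SimConfig.d_true missing condition {c!r}")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def _trial_counts(config: SimConfig) -> dict:
    counts = {x: config.trials_per_intensity for x in config.intensities}
    if 120 in counts:
        counts[120] += config.extra_trials_120
    return counts


def aurc_population_moments(config: SimConfig) -> tuple[float, float]:
    """Closed-form mean and SD of the pre-intervention AURC across sessions.

    The per-cell geometric-mean amplitude is exp(mu_k + b + eps_k) with
    b ~ N(0, tau_p^2 + tau_s^2 + tau_tp^2) shared across cells and
    eps_k ~ N(0, sigma^2 / n_k) independent across cells; the AURC is the
    trapezoid-weighted sum, whose first two moments follow from log-normal
    moment formulas.
    """
    x = np.asarray(config.intensities, dtype=float)
    mu = recruitment_log_mean(x)
    dx = np.diff(x)
    w = np.zeros_like(x)
    w[:-1] += dx / 2.0
    w[1:] += dx / 2.0
    counts = _trial_counts(config)
    nk = np.array([counts[int(i)] for i in x], dtype=float)
    v_cell = config.sigma_log ** 2 / nk
    v_b = (config.tau_participant ** 2 + config.tau_session ** 2
           + config.tau_timepoint ** 2)

    term = w * np.exp(mu + v_cell / 2.0)
    mean = math.exp(v_b / 2.0) * term.sum()

    cross = np.outer(term, term)
    # same-cell terms need the full (not halved) cell variance
    np.fill_diagonal(cross, w ** 2 * np.exp(2 * mu + 2 * v_cell))
    second = math.exp(2.0 * v_b) * cross.sum()
    var = second - mean ** 2
    return mean, math.sqrt(var)


def effect_log_shift(d: float, config: SimConfig) -> float:
    """Log-amplitude shift producing a population AURC effect size ``d``.

    A uniform multiplicative change e^s scales the AURC by e^s, so
    d = (e^s - 1) * E[AURC] / SD[AURC] and s = log1p(d * cv).
    """
    mean, sd = aurc_population_moments(config)
    cv = sd / mean
    arg = d * cv
    if arg <= -1.0:
        raise ConfigurationError(
            f"d_true = {d} is unattainably negative for cv = {cv:.3f}")
    return math.log1p(arg)


def _contamination_propensity(rng, config: SimConfig) -> float:
    """Per-block contamination probability (Beta-overdispersed Bernoulli)."""
    p, phi = config.contamination_rate, config.contamination_clustering
    if phi == 0.0 or p in (0.0, 1.0):
        return p
    nu = 1.0 / phi - 1.0  # Beta concentration giving var = phi * p * (1 - p)
    return float(rng.beta(p * nu, (1.0 - p) * nu))


def _participant_rng(config: SimConfig, index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(config.seed, spawn_key=(index,))
    return np.random.default_rng(ss)


def generate_dataset(config: SimConfig) -> pd.DataFrame:
    """Generate a trial-level dataset (long format, one row per TMS pulse).

    Columns: participant, condition, timepoint, intensity_pct_rmt, trial,
    mep_fcr_mv, mep_ecr_mv, rms_fcr_uv, rms_ecr_uv.
    """
    counts = _trial_counts(config)
    shifts = {
        (c, tp): (0.0 if tp == "Pre"
                  else effect_log_shift(config.d_true[c].get(tp, 0.0), config))
        for c in config.conditions for tp in config.timepoints
    }

    frames = []
    for pi in range(config.n_participants):
        rng = _participant_rng(config, pi)
        pid = f"P{pi + 1:02d}"
        b_i = rng.normal(0.0, config.tau_participant)
        rms_base = rng.uniform(*config.rms_base_range)
        for cond in config.conditions:
            s_ic = rng.normal(0.0, config.tau_session)
            rms_session = math.exp(rng.normal(0.0, config.rms_session_sd))
            # post-hoc cell deletions for this session
            killed = {
                tp: rng.choice(config.intensities)
                for tp in config.timepoints
                if rng.random() < config.missing_rate
            }
            for tp in config.timepoints:
                shift = shifts[(cond, tp)] + rng.normal(0.0, config.tau_timepoint)
                pi_block = _contamination_propensity(rng, config)
                for x in config.intensities:
                    n = counts[x]
                    mu = recruitment_log_mean(x) + b_i + s_ic + shift
                    amp_fcr = np.exp(rng.normal(mu, config.sigma_log, n))
                    amp_ecr = np.exp(rng.normal(mu + _ECR_OFFSET,
                                                config.sigma_log, n))
                    rms = np.empty((n, 2))
                    contaminated = rng.random(n) < pi_block
                    for m in range(2):
                        clean = np.minimum(
                            rms_base * rms_session
                            * np.exp(rng.normal(0.0, config.rms_trial_sd, n)),
                            _RMS_CLEAN_MAX,
                        )
                        dirty = rng.uniform(*_RMS_CONTAMINATED_RANGE, n)
                        rms[:, m] = np.where(contaminated, dirty, clean)
                    if killed.get(tp) == x:
                        rms[:, :] = _RMS_CONTAMINATED_RANGE[0] + 0.5
                    frames.append(pd.DataFrame({
                        "participant": pid,
                        "condition": cond,
                        "timepoint": tp,
                        "intensity_pct_rmt": int(x),
                        "trial": np.arange(1, n + 1),
                        "mep_fcr_mv": amp_fcr,
                        "mep_ecr_mv": amp_ecr,
                        "rms_fcr_uv": rms[:, 0],
                        "rms_ecr_uv": rms[:, 1],
                    }))
    return pd.concat(frames, ignore_index=True)
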