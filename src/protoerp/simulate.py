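"""Synthetic multi-subject RSVP-EEG cohorts.

Emulates the statistical structure a zero-calibration prototype decoder
relies on: rare targets embedded in frequent nontargets (default 1 : 24),
a P300-like positive deflection present only in target epochs, and
between-subject variation in ERP amplitude, latency and scalp topography,
over temporally colored background noise.

Model per epoch (all channels, microvolts):

* background: independent AR(1) noise per channel,
  ``x[t] = ar_coeff * x[t-1] + eps[t]``, ``eps ~ N(0, noise_sd^2)``,
  initialized from the stationary distribution (a one-parameter stand-in
  for the 1/f-like EEG spectrum);
* target epochs add ``A_s * exp(-(t - L)^2 / (2 w^2)) * topo_s[c]`` where
  the amplitude ``A_s`` and mean latency ``L_s`` are drawn once per
  subject, each trial jitters the latency, and ``topo_s`` is a fixed
  unit-norm centro-parietal base loading plus a per-subject perturbation.

The base topography is a raised cosine over the electrode axis peaking at
channel index ``round(n_channels * 5/8)`` (a "Pz-like" site for a
front-to-back channel ordering), with half-width ``n_channels/4``, zero
elsewhere, normalized to unit Euclidean norm.

Randomness uses one counter-based Philox stream per subject, keyed by
``seed + subject_index``, so a subject's data is independent of cohort
size and reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import EpochSet, SubjectCollection, ValidationError

__all__ = ["SimConfig", "base_topography", "make_subject", "make_cohort"]


@dataclass
class SimConfig:
    n_subjects: int = 6
    trials_per_subject: int = 250
    target_ratio: float = 1.0 / 25.0      # 1 target : 24 nontarget
    sfreq: float = 250.0
    window_s: float = 1.0
    n_channels: int = 16
    erp_amplitude_mean: float = 5.0       # microvolts
    erp_amplitude_subject_sd: float = 1.0
    erp_latency_mean_s: float = 0.35
    erp_latency_subject_sd_s: float = 0.03
    erp_latency_trial_sd_s: float = 0.02
    erp_width_s: float = 0.08
    noise_sd: float = 5.0                 # sd of the AR(1) driving noise
    ar_coeff: float = 0.95
    topography_perturb_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.target_ratio < 0.5):
            raise ValidationError(
                f"target_ratio must be in (0, 0.5), got {self.target_ratio}")
        for name in ("erp_amplitude_subject_sd", "erp_latency_subject_sd_s",
                     "erp_latency_trial_sd_s", "noise_sd",
                     "topography_perturb_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (0.0 <= self.ar_coeff < 1.0):
            raise ValidationError(f"ar_coeff must be in [0, 1), got {self.ar_coeff}")
        if self.sfreq <= 0 or self.window_s <= 0:
            raise ValidationError("sfreq and window_s must be positive")
        if self.n_channels < 1 or self.trials_per_subject < 1:
            raise ValidationError("n_channels and trials_per_subject must be >= 1")
        spread = 3.0 * (self.erp_latency_subject_sd_s + self.erp_latency_trial_sd_s)
        if not (0.0 <= self.erp_latency_mean_s - spread
                and self.erp_latency_mean_s + spread <= self.window_s):
            raise ValidationError(
                "erp_latency_mean_s +/- 3*(subject_sd + trial_sd) must lie "
                "inside the epoch window")

    @property
    def n_samples(self) -> int:
        return int(round(self.window_s * self.sfreq))

    @property
    def n_targets_per_subject(self) -> int:
        return int(round(self.trials_per_subject * self.target_ratio))


def base_topography(n_channels: int) -> np.ndarray:
    """Unit-norm raised-cosine spatial loading peaking at a Pz-like site."""
    peak = int(round(n_channels * 5 / 8))
    half_width = max(n_channels / 4.0, 1.0)
    idx = np.arange(n_channels)
    rel = (idx - peak) / half_width
    topo = np.where(np.abs(rel) <= 1.0, 0.5 * (1.0 + np.cos(np.pi * rel)), 0.0)
    return topo / np.linalg.norm(topo)


def _subject_rng(config: SimConfig, subject_index: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(config.seed + subject_index))


def _ar1_noise(rng: np.random.Generator, shape: tuple, a: float,
               sd: float) -> np.ndarray:
    """Stationary AR(1) noise along the last axis."""
    from scipy.signal import lfilter

    eps = rng.normal(0.0, sd, size=shape)
    out = lfilter([1.0], [1.0, -a], eps, axis=-1)
    # replace the transient start with a stationary initial condition:
    # x0 ~ N(0, sd^2 / (1 - a^2)) propagated through the recursion
    x0 = rng.normal(0.0, sd / np.sqrt(1.0 - a * a), size=shape[:-1])
    decay = a ** np.arange(1, shape[-1] + 1)
    return out + x0[..., None] * decay


def make_subject(config: SimConfig, subject_index: int) -> EpochSet:
    """Simulate one subject's epochs, fully determined by (seed, subject_index)."""
    config.validate()
    rng = _subject_rng(config, subject_index)
    n_trials = config.trials_per_subject
    n_ch, n_samp = config.n_channels, config.n_samples

    # subject-level draws (fixed order for reproducibility)
    amplitude = rng.normal(config.erp_amplitude_mean,
                           config.erp_amplitude_subject_sd)
    latency_s = rng.normal(config.erp_latency_mean_s,
                           config.erp_latency_subject_sd_s)
    topo = base_topography(n_ch) + rng.normal(
        0.0, config.topography_perturb_sd, size=n_ch)

    # label placement
    n_targets = config.n_targets_per_subject
    labels = np.zeros(n_trials, dtype=np.int64)
    target_idx = rng.choice(n_trials, size=n_targets, replace=False)
    labels[target_idx] = 1

    data = _ar1_noise(rng, (n_trials, n_ch, n_samp), config.ar_coeff,
                      config.noise_sd)

    t = np.arange(n_samp) / config.sfreq
    trial_lat = latency_s + rng.normal(0.0, config.erp_latency_trial_sd_s,
                                       size=n_targets)
    profiles = np.exp(-((t[None, :] - trial_lat[:, None]) ** 2)
                      / (2.0 * config.erp_width_s ** 2))
    data[target_idx] += amplitude * topo[None, :, None] * profiles[:, None, :]

    return EpochSet(
        data=data,
        labels=labels,
        subject_id=f"S{subject_index:02d}",
        sfreq=config.sfreq,
        channel_names=[f"CH{c:02d}" for c in range(n_ch)],
    )


def make_cohort(config: SimConfig) -> SubjectCollection:
    """Simulate ``n_subjects`` independent subjects (deterministic per seed)."""
    config.validate()
    if config.n_subjects < 2:
        raise ValidationError(
            "episodic training needs at least 2 subjects; "
            f"got n_subjects={config.n_subjects}")
    subjects = {}
    for i in range(config.n_subjects):
        es = make_subject(config, i)
        subjects[es.subject_id] = es
    return SubjectCollection(subjects)
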