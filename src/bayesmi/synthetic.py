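"""Synthetic EEG and predictive-stack generators.

Two independent fixtures for the decoding stack:

* :func:`generate_eeg` emulates band-limited oscillatory EEG with a
  class-dependent event-related desynchronization (ERD): during the
  motor-imagery window the mu (8-12 Hz) and beta (13-30 Hz) amplitudes on the
  channel group assigned to the trial's class are suppressed by a factor
  ``1 - erd_depth``.  This reproduces the contralateral sensorimotor-rhythm
  suppression that motor-imagery decoders exploit, with none of the
  volume-conduction or artifact structure of real recordings.

* :func:`generate_stacks` draws Monte-Carlo predictive stacks (T score rows
  on the C-simplex) of controllable dispersion around a target mean, so the
  uncertainty and reject-option machinery can be exercised without training
  a model.

All randomness flows from a single seeded :class:`numpy.random.Generator`
per call; identical config + seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .containers import TrialSet

__all__ = ["EEGSimConfig", "StackSimConfig", "generate_eeg", "generate_stacks"]


@dataclass
class EEGSimConfig:
    """Parameters of the synthetic ERD/ERS simulator.

    Amplitudes are in arbitrary microvolt-like units; what matters for the
    decoder is the oscillation-to-background ratio.  The trial span defaults
    to [-1.5, 8.0] s around the cue so the full crop range (last crop start
    3.996 s + 4 s length) fits inside every trial.
    """

    n_trials_per_class: int = 40
    n_classes: int = 2
    n_channels: int = 3
    fs: float = 250.0
    trial_start_s: float = -1.5
    trial_end_s: float = 8.0
    background_noise_sd: float = 1.0
    mu_band: tuple[float, float] = (8.0, 12.0)
    beta_band: tuple[float, float] = (13.0, 30.0)
    mu_amp: float = 2.0
    beta_amp: float = 1.0
    erd_depth: float = 0.8
    erd_onset_s: float = 0.5
    erd_offset_s: float = 4.5
    erd_ramp_s: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes not in (2, 4):
            raise ValueError("n_classes must be 2 or 4")
        if self.n_trials_per_class < 1 or self.n_channels < 1:
            raise ValueError("need at least one trial per class and one channel")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for lo, hi in (self.mu_band, self.beta_band):
            if not (0 < lo < hi < self.fs / 2):
                raise ValueError(f"invalid band edges ({lo}, {hi}) at fs={self.fs}")
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must lie in [0, 1]")
        if self.trial_start_s > -0.5 or self.trial_end_s < 8.0:
            raise ValueError(
                "trial span must cover [-0.5, 8.0] s so that 4-s crops starting "
                "up to 4 s after the cue fit inside the trial"
            )
        if not (self.trial_start_s < self.erd_onset_s < self.erd_offset_s
                <= self.trial_end_s):
            raise ValueError("ERD window must lie inside the trial span")


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                band: tuple[float, float]) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band`` (FFT mask)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spec[~mask] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance 1/f-shaped noise (flat below 1 Hz to bound power)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec /= np.sqrt(np.maximum(freqs, 1.0))
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _erd_envelope(t: np.ndarray, cfg: EEGSimConfig) -> np.ndarray:
    """Amplitude factor over time: 1 outside the MI window, 1 - erd_depth
    inside, with raised-cosine ramps of erd_ramp_s at both edges."""
    r = max(cfg.erd_ramp_s, 1e-9)
    up = np.clip((t - cfg.erd_onset_s) / r, 0.0, 1.0)
    down = np.clip((cfg.erd_offset_s - t) / r, 0.0, 1.0)
    depth = cfg.erd_depth * (0.5 - 0.5 * np.cos(np.pi * up)) \
        * (0.5 - 0.5 * np.cos(np.pi * down))
    return 1.0 - depth


def channel_class_assignment(n_channels: int, n_classes: int) -> np.ndarray:
    """Deterministic round-robin map: channel k carries the ERD of class
    ``k % n_classes``."""
    return np.arange(n_channels) % n_classes


def generate_eeg(config: EEGSimConfig) -> TrialSet:
    """Simulate a balanced labeled :class:`TrialSet`.

    Each trial is broadband background noise (white + 1/f) plus mu- and
    beta-band oscillations on every channel; on the channels assigned to the
    trial's class the oscillation amplitude is multiplied by
    ``1 - erd_depth`` during the MI window ``[erd_onset_s, erd_offset_s]``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_samples = int(round((config.trial_end_s - config.trial_start_s) * config.fs))
    cue_idx = int(round(-config.trial_start_s * config.fs))
    t = (np.arange(n_samples) - cue_idx) / config.fs
    assign = channel_class_assignment(config.n_channels, config.n_classes)
    envelope = _erd_envelope(t, config)

    n_trials = config.n_trials_per_class * config.n_classes
    labels = np.repeat(np.arange(config.n_classes), config.n_trials_per_class)
    rng.shuffle(labels)

    data = np.empty((n_trials, config.n_channels, n_samples))
    for i in range(n_trials):
        for ch in range(config.n_channels):
            amp = envelope if assign[ch] == labels[i] else 1.0
            osc = (config.mu_amp * _band_noise(rng, n_samples, config.fs, config.mu_band)
                   + config.beta_amp * _band_noise(rng, n_samples, config.fs,
                                                   config.beta_band))
            noise = (rng.standard_normal(n_samples)
                     + _pink_noise(rng, n_samples, config.fs))
            data[i, ch] = amp * osc + config.background_noise_sd * noise / np.sqrt(2)

    return TrialSet(
        data=data,
        labels=labels,
        fs=config.fs,
        cue_onset_index=cue_idx,
        rest_window=(0, cue_idx),
        preprocessed=False,
    )


@dataclass
class StackSimConfig:
    """Parameters of the predictive-stack sampler.

    Rows are drawn from a Dirichlet distribution with mean ``m``, where
    ``m[true_class] = mean_correct_prob`` and the remainder is spread evenly,
    and concentration parameter ``concentration * C * m``.  High concentration
    gives low-dispersion stacks; ``deterministic=True`` is the infinite-
    concentration limit (all rows equal to ``m``).
    """

    n_inputs: int = 100
    n_classes: int = 4
    n_passes: int = 50
    true_class: int | np.ndarray = 0
    concentration: float | np.ndarray = 10.0
    mean_correct_prob: float = 0.7
    deterministic: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.n_passes < 2:
            raise ValueError("need at least two forward passes (T >= 2)")
        if self.n_inputs < 1:
            raise ValueError("need at least one input")
        if np.any(np.asarray(self.concentration) <= 0):
            raise ValueError("concentration must be positive")
        if not (0 < self.mean_correct_prob < 1):
            raise ValueError("mean_correct_prob must lie in (0, 1)")
        tc = np.asarray(self.true_class)
        if np.any(tc < 0) or np.any(tc >= self.n_classes):
            raise ValueError("true_class out of range")


def generate_stacks(config: StackSimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Draw synthetic predictive stacks.

    Returns
    -------
    stacks : (n_inputs, T, C) array of simplex rows
    true_class : (n_inputs,) int array
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    C, T, n = config.n_classes, config.n_passes, config.n_inputs
    true = np.broadcast_to(np.asarray(config.true_class, dtype=np.int64), (n,)).copy()
    conc = np.broadcast_to(np.asarray(config.concentration, dtype=np.float64),
                           (n,)).copy()

    p, q = config.mean_correct_prob, (1 - config.mean_correct_prob) / (C - 1)
    stacks = np.empty((n, T, C))
    for i in range(n):
        m = np.full(C, q)
        m[true[i]] = p
        if config.deterministic:
            stacks[i] = np.tile(m, (T, 1))
        else:
            stacks[i] = rng.dirichlet(conc[i] * C * m, size=T)
    return stacks, true
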