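"""EEG preprocessing: band-pass filter, exponential moving standardization,
and cropped data augmentation.

Pipeline order is fixed: filter -> clip + standardize -> crop.

The standardization is the electrode-wise exponential moving scheme used in
online-plausible EEG decoders: per channel, running mean and variance are
seeded from the rest period preceding the cue and then updated sample by
sample with decay ``lambda``; each incoming amplitude is first clipped to
``mu +/- clip_factor * sigma`` using the statistics available *before* the
update, and the output is the clipped value standardized by the *updated*
statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .containers import CropSet, TrialSet

__all__ = ["PreprocessConfig", "bandpass", "exp_moving_standardize", "crop",
           "preprocess"]


@dataclass
class PreprocessConfig:
    band_low: float = 4.0            # Hz
    band_high: float = 38.0          # Hz
    filter_order: int = 4
    zero_phase: bool = False         # forward-backward filtering if True
    decay: float = 0.999             # lambda of the moving standardization
    clip_factor: float = 6.0         # outliers limited to mu +/- 6 sigma
    variance_floor: float = 1e-8
    crop_len_s: float = 4.0
    crop_stride_s: float = 0.008
    crop_start_s: float = -0.5
    crop_start_end_s: float = 4.0    # largest allowed crop *start* time

    def validate(self, fs: float) -> None:
        if not (0 < self.band_low < self.band_high < fs / 2):
            raise ValueError(
                f"band ({self.band_low}, {self.band_high}) Hz must satisfy "
                f"0 < low < high < Nyquist ({fs / 2} Hz)")
        if not 0 < self.decay < 1:
            raise ValueError("decay must lie in (0, 1)")
        if self.clip_factor <= 0:
            raise ValueError("clip_factor must be positive")
        L = self.crop_len_s * fs
        if abs(L - round(L)) > 1e-9 or round(L) < 1:
            raise ValueError("crop_len_s * fs must be a positive integer")
        if self.crop_start_end_s < self.crop_start_s:
            raise ValueError("crop_start_end_s must be >= crop_start_s")


def bandpass(trials: TrialSet, config: PreprocessConfig) -> TrialSet:
    """4th-order Butterworth band-pass, applied per channel.

    Causal (single forward pass) by default; set ``config.zero_phase`` for
    forward-backward filtering.
    """
    config.validate(trials.fs)
    sos = signal.butter(config.filter_order,
                        [config.band_low, config.band_high],
                        btype="bandpass", fs=trials.fs, output="sos")
    filt = signal.sosfiltfilt if config.zero_phase else signal.sosfilt
    data = filt(sos, trials.data, axis=-1)
    return TrialSet(data=np.ascontiguousarray(data), labels=trials.labels,
                    fs=trials.fs, cue_onset_index=trials.cue_onset_index,
                    rest_window=trials.rest_window, preprocessed=False)


def exp_moving_standardize(trials: TrialSet,
                           config: PreprocessConfig) -> TrialSet:
    """Electrode-wise exponential moving standardization with outlier
    rectification.

    Per trial and channel, with decay ``lam``:

    - seed ``mu, var`` with the mean/variance over the rest window;
    - for each sample ``x`` in order: clip ``x`` to
      ``mu +/- clip_factor * sqrt(var)`` (pre-update statistics), then
      ``mu <- lam*mu + (1-lam)*x_c``,
      ``var <- lam*var + (1-lam)*(x_c - mu)**2``,
      output ``(x_c - mu) / sqrt(var)``.
    """
    if trials.preprocessed:
        raise ValueError("trials are already standardized")
    lam = config.decay
    k = config.clip_factor
    lo, hi = trials.rest_window
    x = trials.data
    mu = x[:, :, lo:hi].mean(axis=-1)
    var = x[:, :, lo:hi].var(axis=-1)
    if np.any(var < config.variance_floor):
        warnings.warn("rest-window variance below floor; flooring",
                      RuntimeWarning, stacklevel=2)
        var = np.maximum(var, config.variance_floor)

    out = np.empty_like(x)
    for i in range(trials.n_samples):
        sd = np.sqrt(var)
        xc = np.clip(x[:, :, i], mu - k * sd, mu + k * sd)
        mu = lam * mu + (1 - lam) * xc
        var = lam * var + (1 - lam) * (xc - mu) ** 2
        var = np.maximum(var, config.variance_floor)
        out[:, :, i] = (xc - mu) / np.sqrt(var)

    return TrialSet(data=out, labels=trials.labels, fs=trials.fs,
                    cue_onset_index=trials.cue_onset_index,
                    rest_window=trials.rest_window, preprocessed=True)


def crop_grid(config: PreprocessConfig, fs: float) -> tuple[np.ndarray, int]:
    """Crop start offsets (samples relative to cue) and crop length L."""
    L = int(round(config.crop_len_s * fs))
    start = int(round(config.crop_start_s * fs))
    end = int(round(config.crop_start_end_s * fs))
    stride = max(int(round(config.crop_stride_s * fs)), 1)
    starts = np.arange(start, end + 1, stride)
    return starts, L


def crop(trials: TrialSet, config: PreprocessConfig) -> CropSet:
    """Extract fixed-length crops on a regular start grid.

    Start times run from ``crop_start_s`` up to the largest grid point
    <= ``crop_start_end_s`` in steps of ``crop_stride_s``; each crop spans
    the half-open interval [start, start + crop_len) and inherits its
    trial's label.  With the defaults at 250 Hz this yields 563 crops of
    1000 samples per trial, the last starting at 3.996 s.
    """
    config.validate(trials.fs)
    starts, L = crop_grid(config, trials.fs)
    first = trials.cue_onset_index + starts[0]
    last = trials.cue_onset_index + starts[-1] + L
    if first < 0 or last > trials.n_samples:
        need_lo = -starts[0] / trials.fs
        need_hi = (starts[-1] + L) / trials.fs
        raise ValueError(
            f"trial span too short for cropping: need samples covering "
            f"[{-need_lo:+.3f}, {need_hi:+.3f}] s around the cue")

    n_per = len(starts)
    n_crops = trials.n_trials * n_per
    crops = np.empty((n_crops, trials.n_channels, L))
    for j, s in enumerate(starts):
        a = trials.cue_onset_index + s
        crops[j::n_per] = trials.data[:, :, a:a + L]
    # index layout: crop j of trial i sits at i * n_per + j
    trial_index = np.repeat(np.arange(trials.n_trials), n_per)
    position = np.tile(np.arange(n_per), trials.n_trials)
    start_s = np.tile(starts / trials.fs, trials.n_trials)
    labels = np.repeat(trials.labels, n_per)
    return CropSet(crops=crops, trial_index=trial_index,
                   crop_position=position, start_time_s=start_s,
                   labels=labels, fs=trials.fs)


def preprocess(trials: TrialSet, config: PreprocessConfig) -> CropSet:
    """Full pipeline: band-pass -> standardize -> crop."""
    return crop(exp_moving_standardize(bandpass(trials, config), config), config)
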