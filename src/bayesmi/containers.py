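"""Core data containers shared across the pipeline.

Conventions: trials are stored ``(n_trials, n_channels, n_samples)``, crops
``(n_crops, n_channels, crop_len)``, predictive stacks ``(T, C)``.  Class
labels are 0-based integers in ``{0..C-1}``.  Sample indices are relative to
the start of the stored trial window; ``cue_onset_index`` marks t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TrialSet:
    """Labeled multi-channel EEG trials.

    data : float array (n_trials, n_channels, n_samples), microvolts before
        standardization and unitless after.
    labels : int array (n_trials,), values in {0..C-1}.
    fs : sampling rate in Hz.
    cue_onset_index : sample index of the task cue (t = 0 s).
    rest_window : (start, stop) half-open sample interval preceding the cue
        used to seed the running standardization statistics.
    preprocessed : True once the trials have been standardized.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    cue_onset_index: int
    rest_window: tuple[int, int]
    preprocessed: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError("labels must have one entry per trial")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("trial data contains non-finite values")
        lo, hi = self.rest_window
        if not (0 <= lo < hi <= self.cue_onset_index):
            raise ValueError("rest_window must precede the cue onset")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def times(self) -> np.ndarray:
        """Sample times in seconds relative to the cue."""
        return (np.arange(self.n_samples) - self.cue_onset_index) / self.fs

    def subset(self, idx: np.ndarray) -> "TrialSet":
        return TrialSet(
            data=self.data[idx],
            labels=self.labels[idx],
            fs=self.fs,
            cue_onset_index=self.cue_onset_index,
            rest_window=self.rest_window,
            preprocessed=self.preprocessed,
        )


@dataclass
class CropSet:
    """Fixed-length crops cut from trials for data augmentation.

    crops : float array (n_crops, n_channels, L).
    trial_index : originating trial of each crop.
    crop_position : 0-based ordinal of the crop within its trial.
    start_time_s : crop start time in seconds relative to the cue.
    labels : class label inherited from the trial.
    """

    crops: np.ndarray
    trial_index: np.ndarray
    crop_position: np.ndarray
    start_time_s: np.ndarray
    labels: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        n = self.crops.shape[0]
        for name in ("trial_index", "crop_position", "start_time_s", "labels"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have one entry per crop")

    @property
    def n_crops(self) -> int:
        return self.crops.shape[0]

    @property
    def crop_len(self) -> int:
        return self.crops.shape[2]

    @property
    def crops_per_trial(self) -> int:
        return int(self.crop_position.max()) + 1

    def subset(self, mask: np.ndarray) -> "CropSet":
        return CropSet(
            crops=self.crops[mask],
            trial_index=self.trial_index[mask],
            crop_position=self.crop_position[mask],
            start_time_s=self.start_time_s[mask],
            labels=self.labels[mask],
            fs=self.fs,
        )

    def for_trials(self, trial_ids: np.ndarray) -> "CropSet":
        return self.subset(np.isin(self.trial_index, trial_ids))


def check_stack(stack: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Validate a predictive stack: T x C rows on the probability simplex."""
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 2 or stack.shape[0] < 1 or stack.shape[1] < 2:
        raise ValueError("stack must be a T x C array with C >= 2")
    if np.any(stack < -tol):
        raise ValueError("stack rows must be nonnegative")
    if np.any(np.abs(stack.sum(axis=1) - 1.0) > tol):
        raise ValueError("stack rows must sum to 1")
    return stack
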