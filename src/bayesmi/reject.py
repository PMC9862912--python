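"""Classification with a reject option: adaptive margin threshold and the
exhaustive entropy-threshold sweep baseline.

The adaptive scheme treats the T per-pass margins d_t of an input as a
sample and asks whether their expectation exceeds zero — a one-sided
one-sample z-test.  The test statistic is zeta = M / (sigma_d / sqrt(T));
the prediction is *certain* (accepted) iff M strictly exceeds the adaptive
threshold

    T_M = sigma_d * z_{1-alpha} / sqrt(T),

where z_{1-alpha} is the standard-normal quantile at confidence 1-alpha.
The threshold adapts to each input's own predictive dispersion and is
conservative: perfectly consistent passes (sigma_d ~ 0) are accepted
whenever M > 0, and at the degenerate boundary M = T_M = 0 the input is
rejected.

The baseline sweeps a fixed threshold Th over a grid, rejecting inputs
whose normalized predictive entropy exceeds Th, and keeps the Th that
maximizes the uncertainty accuracy UA on a validation set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .uncertainty import UncertaintySummary

__all__ = ["ThresholdConfig", "adaptive_threshold", "decide", "decide_batch",
           "sweep_threshold"]


@dataclass
class ThresholdConfig:
    alpha: float = 0.05          # significance level; confidence = 1 - alpha
    use_t: bool = False          # exact small-sample variant (t with T-1 df)
    grid_lo: float = 0.05
    grid_hi: float = 1.0
    grid_step: float = 0.01

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 <= self.grid_lo < self.grid_hi):
            raise ValueError("sweep grid bounds must satisfy 0 <= lo < hi")
        if self.grid_step <= 0:
            raise ValueError("grid step must be positive")

    def grid(self) -> np.ndarray:
        return np.arange(self.grid_lo, self.grid_hi + self.grid_step / 2,
                         self.grid_step)


def _quantile(alpha: float, T: int, use_t: bool) -> float:
    if use_t:
        return float(stats.t.ppf(1.0 - alpha, df=T - 1))
    return float(stats.norm.ppf(1.0 - alpha))


def adaptive_threshold(sigma_d: float | np.ndarray, T: int,
                       alpha: float = 0.05, use_t: bool = False) -> float | np.ndarray:
    """T_M = sigma_d * z_{1-alpha} / sqrt(T) (vectorized over sigma_d)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if T < 2:
        raise ValueError("need T >= 2")
    if np.any(np.asarray(sigma_d) < 0):
        raise ValueError("sigma_d must be nonnegative")
    tm = np.asarray(sigma_d) * _quantile(alpha, T, use_t) / np.sqrt(T)
    return float(tm) if np.isscalar(sigma_d) else tm


def decide(summary: UncertaintySummary, config: ThresholdConfig) -> bool:
    """True iff the prediction is certain: M > T_M (strict).

    Equivalent to rejecting H0: E[d] <= 0 at level alpha when sigma_d > 0;
    with sigma_d = 0 the input is certain iff M > 0.
    """
    config.validate()
    tm = adaptive_threshold(summary.sigma_d, summary.T, config.alpha,
                            config.use_t)
    return bool(summary.M > tm)


def decide_batch(M: np.ndarray, sigma_d: np.ndarray, T: int,
                 config: ThresholdConfig) -> np.ndarray:
    """Vectorized :func:`decide` over per-input margin statistics."""
    config.validate()
    tm = adaptive_threshold(np.asarray(sigma_d), T, config.alpha, config.use_t)
    return np.asarray(M) > tm


def sweep_threshold(hn: np.ndarray, correct: np.ndarray,
                    config: ThresholdConfig) -> tuple[float, np.ndarray, np.ndarray]:
    """Exhaustive search for the entropy threshold maximizing UA.

    For each grid value Th, inputs with normalized entropy Hn > Th are
    rejected (uncertain) and UA = (N_cc + N_iu) / N is evaluated; returns
    ``(best_th, grid, ua_curve)`` with ties broken toward the smallest Th.
    """
    config.validate()
    hn = np.asarray(hn, dtype=np.float64)
    correct = np.asarray(correct, dtype=bool)
    if hn.size == 0 or hn.shape != correct.shape:
        raise ValueError("hn and correct must be equal-length, non-empty")
    if np.any(hn < 0) or np.any(hn > 1 + 1e-9):
        raise ValueError("normalized entropies must lie in [0, 1]")
    grid = config.grid()
    certain = hn[None, :] <= grid[:, None]            # (n_grid, n_inputs)
    ua = np.where(certain, correct[None, :], ~correct[None, :]).mean(axis=1)
    best = int(np.argmax(ua))                         # argmax -> smallest index
    return float(grid[best]), grid, ua
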