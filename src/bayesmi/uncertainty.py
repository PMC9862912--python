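"""Uncertainty measures over Monte-Carlo predictive stacks.

A predictive stack is the (T, C) array of softmax rows from T stochastic
forward passes on one input.  From it we compute:

* the mean prediction ``y*`` (column mean) and predicted class
  ``c = argmax y*`` (ties broken by lowest index);
* the predictive entropy ``H = -sum_j y*_j log2 y*_j`` in bits and its
  normalization ``Hn = H / log2 C`` in [0, 1];
* the mutual information ``I = H - mean_t H(y_t)`` (epistemic term: zero
  when every pass agrees);
* the per-pass margins ``d_t = y_t[c] - max_{j != c} y_t[j]`` with mean
  margin ``M`` and sample (n-1) standard deviation ``sigma_d``.

Entropies use base-2 logs with 0*log 0 := 0 (scores clamped to 1e-12
inside logs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import check_stack

__all__ = ["UncertaintySummary", "mean_prediction", "predictive_entropy",
           "mutual_information", "margin_stats", "summarize"]

_CLAMP = 1e-12


@dataclass
class UncertaintySummary:
    """Per-input uncertainty summary (see module docstring for symbols)."""

    y_star: np.ndarray
    predicted_class: int
    H: float
    Hn: float
    I: float
    d: np.ndarray
    M: float
    sigma_d: float
    T: int
    tie: bool = False


def _entropy_bits(p: np.ndarray, axis: int = -1) -> np.ndarray:
    q = np.clip(p, _CLAMP, 1.0)
    return -(np.where(p > 0, p * np.log2(q), 0.0)).sum(axis=axis) + 0.0


def mean_prediction(stack: np.ndarray) -> tuple[np.ndarray, int]:
    """Column mean of the stack and the argmax class (lowest index on ties)."""
    stack = check_stack(stack)
    y_star = stack.mean(axis=0)
    return y_star, int(np.argmax(y_star))


def predictive_entropy(y_star: np.ndarray, tol: float = 1e-6) -> tuple[float, float]:
    """Base-2 entropy of the mean prediction and its normalization Hn = H/log2 C."""
    y_star = np.asarray(y_star, dtype=np.float64)
    if y_star.ndim != 1 or y_star.shape[0] < 2:
        raise ValueError("y_star must be a probability vector with C >= 2")
    if np.any(y_star < -tol) or abs(y_star.sum() - 1.0) > tol:
        raise ValueError("y_star is off the probability simplex")
    H = float(_entropy_bits(y_star))
    return H, H / np.log2(y_star.shape[0])


def mutual_information(stack: np.ndarray) -> float:
    """Epistemic term: entropy of the mean minus mean per-pass entropy (bits)."""
    stack = check_stack(stack)
    H = _entropy_bits(stack.mean(axis=0))
    return float(H - _entropy_bits(stack, axis=1).mean())


def margin_stats(stack: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Per-pass margins against the class predicted by the mean.

    The predicted class c is fixed from the column mean; for each pass,
    ``d_t = y_t[c] - max_{j != c} y_t[j]`` (negative when another class wins
    that pass).  Returns (d, M, sigma_d) with sigma_d the n-1 sample
    standard deviation; requires T >= 2.
    """
    stack = check_stack(stack)
    if stack.shape[0] < 2:
        raise ValueError("need T >= 2 passes for a sample standard deviation")
    _, c = mean_prediction(stack)
    others = np.delete(stack, c, axis=1)
    d = stack[:, c] - others.max(axis=1)
    return d, float(d.mean()), float(d.std(ddof=1))


def summarize(stack: np.ndarray) -> UncertaintySummary:
    """All uncertainty measures for one stack."""
    stack = check_stack(stack)
    y_star = stack.mean(axis=0)
    c = int(np.argmax(y_star))
    tie = bool((np.isclose(y_star, y_star[c])).sum() > 1)
    H, Hn = predictive_entropy(y_star)
    I = mutual_information(stack)
    d, M, sigma_d = margin_stats(stack)
    return UncertaintySummary(y_star=y_star, predicted_class=c, H=H, Hn=Hn,
                              I=I, d=d, M=M, sigma_d=sigma_d,
                              T=stack.shape[0], tie=tie)
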