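"""Evaluation framework: reject-option metrics, repeated-holdout protocol,
crop-position uncertainty profiles, and the end-to-end experiment driver.

Every prediction falls into one of four cells by crossing correctness with
the accept/reject decision — correct-certain (cc), incorrect-certain (ic),
correct-uncertain (cu), incorrect-uncertain (iu) — from which the criteria

    Rc  = (Ncc + Nic) / N          coverage (certain rate)
    Rcc = Ncc / (Ncc + Nic)        accuracy on accepted inputs
    Rcu = Ncu / (Ncu + Niu)        accuracy on rejected inputs
    UA  = (Ncc + Niu) / N          uncertainty accuracy

are computed.  Two identities tie them together and are enforced by tests:
``accuracy = Rc*Rcc + (1-Rc)*Rcu`` and ``UA = Rc*Rcc + (1-Rc)*(1-Rcu)``.

Splits are performed at the *trial* level: overlapping crops of one trial
are near-duplicates, so crop-level splitting would leak between training
and validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import model as mdl
from . import preprocessing as pp
from .containers import CropSet, TrialSet
from .reject import ThresholdConfig, decide_batch, sweep_threshold
from .uncertainty import _entropy_bits, margin_stats

__all__ = ["RejectCounts", "RejectMetrics", "ExperimentPlan", "categorize",
           "reject_metrics", "holdout_split", "crop_uncertainty_profile",
           "central_crop_positions", "central_crop_predict", "stack_summaries",
           "run_experiment"]


@dataclass
class RejectCounts:
    n_cc: int
    n_ic: int
    n_cu: int
    n_iu: int

    def __post_init__(self) -> None:
        if min(self.n_cc, self.n_ic, self.n_cu, self.n_iu) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.n_cc + self.n_ic + self.n_cu + self.n_iu


@dataclass
class RejectMetrics:
    """Reject-option criteria; Rcc/Rcu are None when their denominator is 0."""

    rc: float
    rcc: float | None
    rcu: float | None
    ua: float
    accuracy: float


@dataclass
class ExperimentPlan:
    strategy: str = "subject_specific"   # or "non_subject_specific" (pooled)
    n_repetitions: int = 16
    val_fraction: float = 0.2
    stratified: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.strategy not in ("subject_specific", "non_subject_specific"):
            raise ValueError("unknown strategy")
        if self.n_repetitions < 1:
            raise ValueError("need at least one repetition")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must lie in (0, 1)")


def categorize(correct: np.ndarray, certain: np.ndarray) -> RejectCounts:
    """Cross-tabulate correctness with the accept decision."""
    correct = np.asarray(correct, dtype=bool)
    certain = np.asarray(certain, dtype=bool)
    if correct.shape != certain.shape:
        raise ValueError("correct/certain length mismatch")
    return RejectCounts(
        n_cc=int(np.sum(correct & certain)),
        n_ic=int(np.sum(~correct & certain)),
        n_cu=int(np.sum(correct & ~certain)),
        n_iu=int(np.sum(~correct & ~certain)),
    )


def reject_metrics(counts: RejectCounts) -> RejectMetrics:
    if counts.n == 0:
        raise ValueError("no predictions to evaluate")
    n_cert = counts.n_cc + counts.n_ic
    n_unc = counts.n_cu + counts.n_iu
    return RejectMetrics(
        rc=n_cert / counts.n,
        rcc=counts.n_cc / n_cert if n_cert else None,
        rcu=counts.n_cu / n_unc if n_unc else None,
        ua=(counts.n_cc + counts.n_iu) / counts.n,
        accuracy=(counts.n_cc + counts.n_cu) / counts.n,
    )


def holdout_split(labels: np.ndarray, plan: ExperimentPlan,
                  repetition: int) -> tuple[np.ndarray, np.ndarray]:
    """Stratified trial-level validation split for one repetition.

    Returns (train_idx, val_idx) over trials, preserving per-class ratios
    (floor of val_fraction per class, at least 1); deterministic in
    (plan.seed, repetition).
    """
    plan.validate()
    labels = np.asarray(labels)
    rng = np.random.default_rng([plan.seed, repetition])
    val_idx: list[np.ndarray] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        n_val = max(int(np.floor(plan.val_fraction * len(idx))), 1) \
            if plan.stratified else int(round(plan.val_fraction * len(idx)))
        if len(idx) - n_val < 1:
            raise ValueError(f"class {cls} has too few trials to split")
        val_idx.append(rng.choice(idx, size=n_val, replace=False))
    val = np.sort(np.concatenate(val_idx))
    train = np.setdiff1d(np.arange(len(labels)), val)
    return train, val


def stack_summaries(stacks: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized uncertainty summaries for (n, T, C) stacks."""
    n, T, C = stacks.shape
    y_star = stacks.mean(axis=1)
    pred = y_star.argmax(axis=1)
    H = _entropy_bits(y_star)
    Hn = H / np.log2(C)
    I = H - _entropy_bits(stacks, axis=2).mean(axis=1)
    masked = stacks.copy()
    masked[np.arange(n)[:, None], np.arange(T)[None, :], pred[:, None]] = -np.inf
    d = stacks[np.arange(n)[:, None], np.arange(T)[None, :], pred[:, None]] \
        - masked.max(axis=2)
    return {"y_star": y_star, "pred": pred, "H": H, "Hn": Hn, "I": I,
            "d": d, "M": d.mean(axis=1), "sigma_d": d.std(axis=1, ddof=1)}


def crop_uncertainty_profile(hn: np.ndarray, crop_position: np.ndarray) -> np.ndarray:
    """Mean normalized entropy at each crop position.

    ``hn`` and ``crop_position`` are aligned per-crop vectors; every
    position must occur equally often (a complete trials x positions grid).
    """
    hn = np.asarray(hn, dtype=np.float64)
    pos = np.asarray(crop_position)
    if hn.shape != pos.shape:
        raise ValueError("hn/crop_position length mismatch")
    positions, counts = np.unique(pos, return_counts=True)
    if len(set(counts)) != 1:
        raise ValueError("ragged crop positions: every trial must contribute "
                         "every position")
    profile = np.zeros(len(positions))
    for i, p in enumerate(positions):
        profile[i] = hn[pos == p].mean()
    return profile


def central_crop_positions(n_positions: int, k: int = 5) -> np.ndarray:
    """The k crop positions centered on the middle one (0-based).

    For even counts the window sits one position left of center.  With the
    default 563 positions and k = 5 this selects 279..283 (0-based).
    """
    if not 1 <= k <= n_positions:
        raise ValueError("k must lie in [1, crops per trial]")
    center = (n_positions - 1) // 2
    start = min(max(center - (k - 1) // 2, 0), n_positions - k)
    return np.arange(start, start + k)


def central_crop_predict(stacks: np.ndarray, crop_position: np.ndarray,
                         k: int = 5) -> tuple[np.ndarray, int, np.ndarray]:
    """Trial-level prediction from the k central crops of one trial.

    ``stacks`` is (n_crops_in_trial, T, C) aligned with ``crop_position``.
    The T-pass stacks of the selected crops are pooled (concatenated) and
    averaged; returns (y_star, predicted_class, pooled_stack) so a reject
    decision can be applied to the pooled stack.
    """
    pos = np.asarray(crop_position)
    n_positions = len(pos)
    sel = central_crop_positions(n_positions, k)
    order = np.argsort(pos)
    chosen = order[np.isin(pos[order], sel)]
    pooled = stacks[chosen].reshape(-1, stacks.shape[2])
    y_star = pooled.mean(axis=0)
    return y_star, int(np.argmax(y_star)), pooled


@dataclass
class RepetitionResult:
    metrics_adaptive: RejectMetrics
    metrics_sweep: RejectMetrics
    best_th: float
    val_accuracy: float
    test_accuracy: float
    history: mdl.TrainingHistory


def _crops_to_x(crops: CropSet) -> np.ndarray:
    return np.ascontiguousarray(crops.crops.transpose(0, 2, 1))


def run_experiment(train_trials: TrialSet, test_trials: TrialSet,
                   plan: ExperimentPlan,
                   pre_cfg: pp.PreprocessConfig,
                   arch: mdl.ArchitectureSpec,
                   train_cfg: mdl.TrainingConfig,
                   thr_cfg: ThresholdConfig,
                   prior_kind: str = "moped",
                   pretrain_cfg: mdl.TrainingConfig | None = None) -> dict:
    """Repeated-holdout experiment with adaptive and swept thresholds.

    For each repetition: split the training trials (trial-level,
    stratified), preprocess, train (a deterministic pretrain feeds the
    MOPED prior when ``prior_kind='moped'``), run T-pass Monte-Carlo
    prediction on validation and test crops, apply the adaptive margin
    threshold and the UA-maximizing entropy sweep (tuned on validation,
    applied to test), and collect crop-wise metrics.  The report carries
    per-repetition values and their averages.
    """
    plan.validate()
    thr_cfg.validate()
    test_crops = pp.preprocess(test_trials, pre_cfg)
    x_test = _crops_to_x(test_crops)
    reps: list[RepetitionResult] = []

    for i in range(plan.n_repetitions):
        tr_idx, va_idx = holdout_split(train_trials.labels, plan, i)
        assert not np.intersect1d(tr_idx, va_idx).size  # trial-level disjoint
        crops_tr = pp.preprocess(train_trials.subset(tr_idx), pre_cfg)
        crops_va = pp.preprocess(train_trials.subset(va_idx), pre_cfg)
        seed_i = int(np.random.default_rng([plan.seed, 1000 + i])
                     .integers(2 ** 31))

        if prior_kind == "moped":
            det = mdl.build_deterministic(arch, seed=seed_i)
            det_cfg = pretrain_cfg or train_cfg
            mdl.train(det, crops_tr, crops_va, det_cfg)
            prior = mdl.moped_prior(det.copy_weights() | dict(
                zip(("bn.gamma", "bn.beta"),
                    (det.weights["bn.gamma"], det.weights["bn.beta"]))))
            net = mdl.to_bayesian(mdl.build_deterministic(arch, seed=seed_i),
                                  prior)
            net.base.set_bn_state(det.bn_state())
        else:
            prior = mdl.PriorSpec(kind="standard")
            net = mdl.to_bayesian(mdl.build_deterministic(arch, seed=seed_i),
                                  prior)
        cfg_i = mdl.TrainingConfig(**{**train_cfg.__dict__, "seed": seed_i})
        hist = mdl.train(net, crops_tr, crops_va, cfg_i)

        T = train_cfg.t_predict
        stacks_va = mdl.mc_predict_many(net, _crops_to_x(crops_va), T=T,
                                        seed=seed_i + 1)
        stacks_te = mdl.mc_predict_many(net, x_test, T=T, seed=seed_i + 2)
        s_va = stack_summaries(stacks_va)
        s_te = stack_summaries(stacks_te)
        correct_va = s_va["pred"] == crops_va.labels
        correct_te = s_te["pred"] == test_crops.labels

        certain_te = decide_batch(s_te["M"], s_te["sigma_d"], T, thr_cfg)
        m_adapt = reject_metrics(categorize(correct_te, certain_te))

        best_th, _, _ = sweep_threshold(s_va["Hn"], correct_va, thr_cfg)
        m_sweep = reject_metrics(
            categorize(correct_te, s_te["Hn"] <= best_th))

        reps.append(RepetitionResult(
            metrics_adaptive=m_adapt, metrics_sweep=m_sweep, best_th=best_th,
            val_accuracy=float(correct_va.mean()),
            test_accuracy=float(correct_te.mean()), history=hist))

    def avg(vals):
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    report = {
        "plan": plan.__dict__ | {"prior_kind": prior_kind},
        "repetitions": [
            {
                "test_accuracy": r.test_accuracy,
                "val_accuracy": r.val_accuracy,
                "best_th": r.best_th,
                "adaptive": r.metrics_adaptive.__dict__,
                "sweep": r.metrics_sweep.__dict__,
                "best_epoch": r.history.best_epoch,
                "best_val_loss": r.history.best_val_loss,
            }
            for r in reps
        ],
    }
    report["mean"] = {
        "test_accuracy": avg([r.test_accuracy for r in reps]),
        "ua_adaptive": avg([r.metrics_adaptive.ua for r in reps]),
        "ua_sweep": avg([r.metrics_sweep.ua for r in reps]),
        "rc_adaptive": avg([r.metrics_adaptive.rc for r in reps]),
        "rcc_adaptive": avg([r.metrics_adaptive.rcc for r in reps]),
        "rcu_adaptive": avg([r.metrics_adaptive.rcu for r in reps]),
    }
    return report
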