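"""Deterministic and Bayesian shallow ConvNets for motor-imagery decoding.

The deterministic baseline (:func:`build_deterministic`) is the shallow
band-power ConvNet; :func:`to_bayesian` replaces every convolutional and
dense weight with an independent Gaussian posterior ``N(mu, sigma^2)``
(mean-field) trained by maximizing the evidence lower bound

    L(theta) = E_q[ln p(Y | X, w)] - KL(q(w, theta) || p(w)),

with the expected log-likelihood estimated by sampling one weight draw per
minibatch (reparameterization) and the KL term in closed form.  Two prior
families are supported: the standard normal ``N(0, 1)`` per weight, and the
MOPED empirical prior ``N(w_d, (0.1 |w_d|)^2)`` built from the pretrained
deterministic weights ``w_d``, which also initializes the posterior.

Monte-Carlo prediction (:func:`mc_predict`) runs T stochastic forward
passes with batch-norm statistics frozen, so all prediction-to-prediction
variability comes from the weight posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import CropSet
from .nn import Adam, ArchitectureSpec, ShallowNet, softmax, softmax_ce_grad, cross_entropy

__all__ = [
    "ArchitectureSpec", "PriorSpec", "TrainingConfig", "TrainingHistory",
    "build_deterministic", "to_bayesian", "moped_prior", "gaussian_kl",
    "elbo_loss", "train", "mc_predict", "mc_predict_many",
    "VariationalShallowNet",
]

_SOFTPLUS_CLIP = 30.0


def softplus(x: np.ndarray) -> np.ndarray:
    return np.where(x > _SOFTPLUS_CLIP, x, np.log1p(np.exp(np.minimum(x, _SOFTPLUS_CLIP))))


def softplus_inv(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=np.float64)
    return np.where(y > _SOFTPLUS_CLIP, y, np.log(np.expm1(np.maximum(y, 1e-12))))


@dataclass
class PriorSpec:
    """Per-weight Gaussian prior family.

    kind="standard": N(0, 1) for every weight.
    kind="moped": N(w_d, max(delta*|w_d|, scale_floor)^2) from pretrained
    deterministic weights; the posterior is initialized at the prior.
    """

    kind: str = "standard"
    moped_delta: float = 0.1
    scale_floor: float = 1e-6
    pretrained_weights: dict[str, np.ndarray] | None = None
    init_scale: float = 0.05   # posterior scale at init for the standard prior

    def validate(self) -> None:
        if self.kind not in ("standard", "moped"):
            raise ValueError("prior kind must be 'standard' or 'moped'")
        if self.moped_delta <= 0:
            raise ValueError("moped delta must be positive")
        if self.scale_floor <= 0:
            raise ValueError("scale_floor must be positive")
        if self.kind == "moped" and self.pretrained_weights is None:
            raise ValueError("MOPED prior requires pretrained weights")


def moped_prior(pretrained_weights: dict[str, np.ndarray],
                delta: float = 0.1, scale_floor: float = 1e-6) -> PriorSpec:
    """Empirical prior from pretrained deterministic weights.

    Each weight w gets prior N(w_d, sigma^2) with sigma = max(delta*|w_d|,
    scale_floor); the absolute value keeps the scale positive for negative
    weights and the floor handles exactly-zero weights.
    """
    spec = PriorSpec(kind="moped", moped_delta=delta, scale_floor=scale_floor,
                     pretrained_weights={k: np.asarray(v, dtype=np.float64)
                                         for k, v in pretrained_weights.items()})
    spec.validate()
    return spec


def gaussian_kl(mu_q: np.ndarray, sigma_q: np.ndarray,
                mu_p: np.ndarray, sigma_p: np.ndarray) -> np.ndarray:
    """Elementwise KL(N(mu_q, sigma_q^2) || N(mu_p, sigma_p^2)), in nats."""
    return (np.log(sigma_p / sigma_q)
            + (sigma_q ** 2 + (mu_q - mu_p) ** 2) / (2.0 * sigma_p ** 2) - 0.5)


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 20            # early stopping on validation loss
    lr_decay_factor: float = 0.5
    lr_decay_patience: int = 10
    kl_weight: float | None = None   # None -> 1 / n_train
    t_predict: int = 50
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("invalid optimizer settings")
        if self.kl_weight is not None and self.kl_weight <= 0:
            raise ValueError("kl_weight must be positive")
        if self.t_predict < 2:
            raise ValueError("t_predict must be at least 2")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1          # 0-based epoch of the best validation loss
    best_val_loss: float = np.inf

    def epochs_to_reach(self, loss: float) -> int | None:
        """First 1-based epoch with validation loss <= ``loss`` (None if never)."""
        for i, v in enumerate(self.val_loss):
            if v <= loss:
                return i + 1
        return None


def build_deterministic(spec: ArchitectureSpec, seed: int = 0) -> ShallowNet:
    """Build the deterministic shallow ConvNet (Glorot-uniform init)."""
    return ShallowNet(spec, np.random.default_rng(seed))


class VariationalShallowNet:
    """Mean-field Gaussian wrapper around :class:`ShallowNet`.

    Convolutional and dense weights carry (mu, rho) variational parameters
    with sigma = softplus(rho) > 0 by construction; batch-norm gamma/beta
    remain point parameters.  A forward pass samples one weight draw
    w = mu + sigma * eps and runs the base network.
    """

    def __init__(self, base: ShallowNet, prior: PriorSpec):
        prior.validate()
        self.base = base
        self.prior_spec = prior
        self.mu: dict[str, np.ndarray] = {}
        self.rho: dict[str, np.ndarray] = {}
        self.prior_mu: dict[str, np.ndarray] = {}
        self.prior_sigma: dict[str, np.ndarray] = {}
        self._eps: dict[str, np.ndarray] = {}

        for k in ShallowNet.WEIGHT_KEYS:
            w0 = base.weights[k]
            if prior.kind == "moped":
                wd = prior.pretrained_weights[k]
                if wd.shape != w0.shape:
                    raise ValueError(f"pretrained weight {k} has shape "
                                     f"{wd.shape}, expected {w0.shape}")
                sigma0 = np.maximum(prior.moped_delta * np.abs(wd),
                                    prior.scale_floor)
                self.mu[k] = wd.copy()
                self.prior_mu[k] = wd.copy()
                self.prior_sigma[k] = sigma0.copy()
            else:
                sigma0 = np.full_like(w0, prior.init_scale)
                self.mu[k] = w0.copy()
                self.prior_mu[k] = np.zeros_like(w0)
                self.prior_sigma[k] = np.ones_like(w0)
            self.rho[k] = softplus_inv(sigma0)
        if prior.kind == "moped" and "bn.gamma" in (prior.pretrained_weights or {}):
            # carry the pretrained batch-norm point parameters and statistics
            for k in ShallowNet.BN_KEYS:
                base.weights[k] = prior.pretrained_weights[k].copy()

    # -- sampling ---------------------------------------------------------

    @property
    def spec(self) -> ArchitectureSpec:
        return self.base.spec

    def sigma(self) -> dict[str, np.ndarray]:
        return {k: softplus(v) for k, v in self.rho.items()}

    def n_variational_parameters(self) -> int:
        return 2 * sum(v.size for v in self.mu.values())

    def sample_weights(self, rng: np.random.Generator) -> None:
        """Draw w = mu + softplus(rho) * eps into the base network."""
        for k in ShallowNet.WEIGHT_KEYS:
            eps = rng.standard_normal(self.mu[k].shape)
            self._eps[k] = eps
            self.base.weights[k] = self.mu[k] + softplus(self.rho[k]) * eps

    def set_mean_weights(self) -> None:
        """Load the posterior means (no sampling) into the base network."""
        for k in ShallowNet.WEIGHT_KEYS:
            self.base.weights[k] = self.mu[k].copy()

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None,
                train: bool = False, sample: bool = True) -> np.ndarray:
        if sample:
            if rng is None:
                raise ValueError("sampling forward pass needs an rng")
            self.sample_weights(rng)
        else:
            self.set_mean_weights()
        return self.base.forward(x, train=train)

    # -- gradients --------------------------------------------------------

    def backward(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients w.r.t. the variational parameters (and BN params) for
        the last sampled forward pass, via the reparameterization chain
        d/d mu = d/dw, d/d rho = d/dw * eps * sigmoid(rho)."""
        gw = self.base.backward(dlogits)
        grads: dict[str, np.ndarray] = {}
        for k in ShallowNet.WEIGHT_KEYS:
            sig = 1.0 / (1.0 + np.exp(-self.rho[k]))
            grads[f"mu:{k}"] = gw[k]
            grads[f"rho:{k}"] = gw[k] * self._eps[k] * sig
        for k in ShallowNet.BN_KEYS:
            grads[k] = gw[k]
        return grads

    def kl(self) -> float:
        """Total closed-form KL(q || p) over all weights, in nats."""
        total = 0.0
        sigmas = self.sigma()
        for k in ShallowNet.WEIGHT_KEYS:
            total += gaussian_kl(self.mu[k], sigmas[k],
                                 self.prior_mu[k], self.prior_sigma[k]).sum()
        return float(total)

    def kl_grads(self) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        for k in ShallowNet.WEIGHT_KEYS:
            sig = softplus(self.rho[k])
            dmu = (self.mu[k] - self.prior_mu[k]) / self.prior_sigma[k] ** 2
            dsig = -1.0 / sig + sig / self.prior_sigma[k] ** 2
            grads[f"mu:{k}"] = dmu
            grads[f"rho:{k}"] = dsig / (1.0 + np.exp(-self.rho[k]))
        return grads

    def parameters(self) -> dict[str, np.ndarray]:
        params = {}
        for k in ShallowNet.WEIGHT_KEYS:
            params[f"mu:{k}"] = self.mu[k]
            params[f"rho:{k}"] = self.rho[k]
        for k in ShallowNet.BN_KEYS:
            params[k] = self.base.weights[k]
        return params


def to_bayesian(model: ShallowNet, prior: PriorSpec) -> VariationalShallowNet:
    """Lift a deterministic net to its mean-field variational counterpart."""
    return VariationalShallowNet(model, prior)


def elbo_loss(logits: np.ndarray, labels: np.ndarray,
              model: VariationalShallowNet, kl_weight: float) -> float:
    """Negative-ELBO minibatch loss: sampled cross-entropy (a one-draw
    Monte-Carlo estimate of the negative expected log-likelihood, per
    sample) plus ``kl_weight`` times the closed-form KL."""
    if logits.shape[0] != len(labels):
        raise ValueError("logits/labels length mismatch")
    if kl_weight <= 0:
        raise ValueError("kl_weight must be positive")
    return cross_entropy(softmax(logits), labels) + kl_weight * model.kl()


def _as_xy(crops: CropSet) -> tuple[np.ndarray, np.ndarray]:
    # network layout is (B, L, c)
    return np.ascontiguousarray(crops.crops.transpose(0, 2, 1)), crops.labels


def _eval_deterministic(net: ShallowNet, x: np.ndarray, y: np.ndarray,
                        batch: int = 256) -> tuple[float, float]:
    losses, correct = [], 0
    for a in range(0, len(x), batch):
        logits = net.forward(x[a:a + batch], train=False)
        p = softmax(logits)
        losses.append(cross_entropy(p, y[a:a + batch]) * len(p))
        correct += int((p.argmax(axis=1) == y[a:a + batch]).sum())
    return sum(losses) / len(x), correct / len(x)


def train(model: ShallowNet | VariationalShallowNet, crops: CropSet,
          val: CropSet, config: TrainingConfig) -> TrainingHistory:
    """Train by Adam on minibatches with early stopping and LR decay.

    Deterministic nets minimize categorical cross-entropy; variational nets
    minimize the negative ELBO with the KL term weighted by ``kl_weight``
    (default 1/n_train).  Validation loss is the plain cross-entropy — at
    the posterior means for variational models — and drives both early
    stopping and learning-rate decay.  The best-validation-loss parameters
    are restored at the end.
    """
    config.validate()
    if crops.n_crops == 0 or val.n_crops == 0:
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    x, y = _as_xy(crops)
    xv, yv = _as_xy(val)
    variational = isinstance(model, VariationalShallowNet)
    kl_w = config.kl_weight if config.kl_weight is not None else 1.0 / len(x)

    params = model.parameters() if variational else {
        k: model.weights[k] for k in (*ShallowNet.WEIGHT_KEYS,
                                      *ShallowNet.BN_KEYS)}
    opt = Adam(params, lr=config.learning_rate)
    hist = TrainingHistory()
    best_state = None
    bad_epochs = plateau = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(x))
        epoch_loss = 0.0
        for a in range(0, len(x), config.batch_size):
            idx = order[a:a + config.batch_size]
            xb, yb = x[idx], y[idx]
            if variational:
                logits = model.forward(xb, rng=rng, train=True)
                ce, dlogits = softmax_ce_grad(logits, yb)
                grads = model.backward(dlogits)
                for k, gk in model.kl_grads().items():
                    grads[k] = grads[k] + kl_w * gk
                loss = ce + kl_w * model.kl()
            else:
                logits = model.forward(xb, train=True)
                loss, dlogits = softmax_ce_grad(logits, yb)
                grads = model.backward(dlogits)
            opt.step(grads)
            epoch_loss += loss * len(idx)
        hist.train_loss.append(epoch_loss / len(x))

        base = model.base if variational else model
        if variational:
            model.set_mean_weights()
        vloss, vacc = _eval_deterministic(base, xv, yv)
        hist.val_loss.append(vloss)
        hist.val_accuracy.append(vacc)

        if vloss < hist.best_val_loss - 1e-12:
            hist.best_val_loss = vloss
            hist.best_epoch = epoch
            bad_epochs = plateau = 0
            snap = {k: v.copy() for k, v in params.items()}
            best_state = (snap, base.bn_state())
        else:
            bad_epochs += 1
            plateau += 1
            if plateau >= config.lr_decay_patience:
                opt.lr *= config.lr_decay_factor
                plateau = 0
            if bad_epochs >= config.patience:
                break

    if best_state is not None:
        snap, bn = best_state
        for k, v in snap.items():
            params[k][...] = v
        (model.base if variational else model).set_bn_state(bn)
    return hist


def mc_predict(model: VariationalShallowNet | ShallowNet, x: np.ndarray,
               T: int = 50, seed: int = 0) -> np.ndarray:
    """Monte-Carlo predictive stack for one input.

    Runs T stochastic forward passes (weights resampled each pass,
    batch-norm frozen in inference mode) and returns the (T, C) stack of
    softmax rows, in draw order.  A deterministic model yields T identical
    rows.
    """
    if T < 2:
        raise ValueError("T must be at least 2")
    if x.ndim == 2:
        x = x[None]
    stacks = mc_predict_many(model, x, T=T, seed=seed)
    return stacks[0]


def mc_predict_many(model: VariationalShallowNet | ShallowNet, x: np.ndarray,
                    T: int = 50, seed: int = 0,
                    batch: int = 256) -> np.ndarray:
    """Predictive stacks for many inputs: returns (n_inputs, T, C).

    One weight draw is shared across all inputs within a pass (the draws
    remain independent across the T passes).
    """
    if T < 2:
        raise ValueError("T must be at least 2")
    rng = np.random.default_rng(seed)
    variational = isinstance(model, VariationalShallowNet)
    n = x.shape[0]
    C = model.spec.n_classes
    out = np.empty((n, T, C))
    for t in range(T):
        if variational:
            model.sample_weights(rng)
            net = model.base
        else:
            net = model
        for a in range(0, n, batch):
            out[a:a + batch, t] = net.predict_proba(x[a:a + batch], train=False)
    return out
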