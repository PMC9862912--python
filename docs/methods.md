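# Methods

## Problem setting

Motor-imagery (MI) BCIs decode which movement a subject imagines from
multi-channel EEG sampled at 250 Hz. Imagined movement suppresses the mu
(8–12 Hz) and beta (13–30 Hz) rhythms over the motor cortex (event-related
desynchronization, ERD), and the decoder's job is to detect which channel
group carries that suppression. Because single trials are noisy and
nonstationary, a practical decoder should also know *when not to answer*.
`bayesmi` couples a variational Bayesian convolutional classifier with a
statistically calibrated reject option.

## Preprocessing

Trials of shape (channels × samples) pass through three stages, in this
fixed order:

1. **Band-pass** 4–38 Hz, fourth-order Butterworth, applied causally
   (single forward pass) per channel. A causal filter keeps the pipeline
   plausible for online use; a zero-phase (forward–backward) option exists
   behind `PreprocessConfig.zero_phase` for offline analyses.
2. **Exponential moving standardization** per electrode with decay
   λ = 0.999. Running mean μ and variance σ² are seeded from the rest
   period preceding the cue; each incoming sample is first clipped to
   μ ± 6σ using the statistics available *before* the update (outlier
   rectification), then the statistics are updated with the clipped value
   and the output is (x_clipped − μ)/σ with the updated statistics. A
   variance floor of 1e−8 protects the division; hitting it raises a
   warning. The clipped value (not the raw one) feeds the update so that a
   single artifact cannot poison the running statistics.
3. **Crop augmentation**: 4-s windows (1000 samples at 250 Hz) on a start
   grid from −0.5 s to 4.0 s in 8-ms steps, all computed on the integer
   sample grid (stride = 2 samples), giving 563 crops per trial with the
   last start at 3.996 s. The grid bounds constrain crop *starts*, so
   source trials must extend to 8.0 s post-cue; the interval convention is
   half-open [start, start + 4 s). Each crop inherits its trial's label.

## Architecture

The deterministic baseline (SCNN) is a shallow band-power ConvNet:

| stage | shape (input 1000 × c) |
|---|---|
| temporal conv, 45×1, 40 filters, stride 2, valid | 478 × c × 40 |
| spatial conv, 1×c across all 40 maps | 478 × 1 × 40 |
| batch-norm → square | 478 × 40 |
| average pool 45, stride 1 | 434 × 40 |
| max pool 8, stride 8 | 54 × 40 |
| log → dense softmax | 2160 → s |

The square → average-pool → log sequence makes the features log band-power
estimates, which is exactly the quantity ERD modulates. The average-pool
stride of 1 and valid (unpadded) convolutions are forced by the shape
arithmetic: (1000−45)//2+1 = 478, 478−45+1 = 434, 434//8·40 = 2160. The
dense width is independent of the electrode count c because the spatial
convolution collapses the electrode axis. The network, its
backpropagation, and the Adam optimizer are implemented directly in numpy;
gradients are verified against finite differences in the test suite.

## Variational training

The Bayesian variants replace every convolutional and dense weight with an
independent Gaussian posterior q(w) = N(μ, σ²), σ = softplus(ρ) > 0 by
construction. Batch-norm scale/offset stay point parameters (they are
normalizers, not representational weights), and dropout/max-norm
regularization of the deterministic baseline is dropped in the Bayesian
models. Training minimizes the negative ELBO

    CE(sampled prediction, labels) + kl_weight · Σ KL(q(w) ‖ p(w)),

with the expected log-likelihood estimated by a single shared weight draw
per minibatch (reparameterization trick, w = μ + σ·ε). This estimator is
unbiased; sharing one draw across the minibatch trades some gradient
variance for speed. The KL term is closed-form Gaussian–Gaussian and is
scaled by `kl_weight` = 1/N_train by default, the standard mean-field
weighting that makes the prior's pull independent of the minibatch count.

Two prior families:

- **standard** — p(w) = N(0, 1) per weight; posterior means start at the
  Glorot initialization with initial scale 0.05.
- **MOPED** — p(w) = N(w_d, max(δ|w_d|, ε)²) with δ = 0.1 and floor
  ε = 1e−6, where w_d are the weights of a pretrained deterministic SCNN;
  the posterior is initialized at the prior. The absolute value handles
  negative weights, the floor handles exact zeros. Pretrained batch-norm
  parameters and running statistics are carried over. Because the
  posterior starts at a good deterministic solution and the KL term is
  zero at initialization, MOPED models start near their final loss; this
  convergence advantage is asserted over three seeds in the test suite.

Early stopping (patience 20 by default, smaller at desk scale) and
plateau-based learning-rate decay (×0.5 after 10 flat epochs) monitor the
validation cross-entropy evaluated *at the posterior means* — a
deterministic, low-variance proxy that makes the best-epoch comparison
between prior families well defined. The best-epoch parameters are
restored after training.

## Monte-Carlo prediction and uncertainty

`mc_predict` runs T = 50 stochastic forward passes with batch-norm frozen
in inference mode, so all variability comes from the weight posterior. The
(T × C) stack of softmax rows yields:

- mean prediction y* (column mean) and predicted class c = argmax y*
  (ties broken to the lowest index and flagged);
- predictive entropy ℍ = −Σ y*_j log₂ y*_j (bits; 0·log 0 := 0, scores
  clamped at 1e−12 inside logs), normalized ℍn = ℍ/log₂C ∈ [0, 1];
- mutual information I = ℍ − (1/T)Σ_t ℍ(y_t), the epistemic part: zero
  when all passes agree, and I ≤ ℍ by Jensen's inequality;
- margins d_t = y_t[c] − max_{j≠c} y_t[j] with c fixed from the mean, mean
  margin M, and sample standard deviation σ_d with the n−1 denominator
  (it feeds a one-sample test statistic).

## Adaptive reject option

Treat the T margins of one input as a sample and test H₀: E[d] ≤ 0 against
H₁: E[d] > 0. The statistic ζ = M/(σ_d/√T) is referred to the standard
normal; the prediction is accepted iff M > T_M with

    T_M = σ_d · z₁₋α / √T,  α = 0.05 by default.

Properties that follow and are verified by simulation in the tests: under
null margins the accept (certain) rate is α (the test is exactly the
one-sided z-test); the threshold adapts to each input's own dispersion;
perfectly consistent passes (σ_d = 0) are accepted whenever M > 0, and the
degenerate boundary M = T_M = 0 rejects (strict inequality); raising the
confidence level 1−α can only grow the rejected set. The normal quantile
is used even though σ_d is estimated; the exact small-sample variant
(Student t with T−1 df) is available via `ThresholdConfig.use_t` but off
by default, matching the published form of the test. At T = 50 the
difference is a type-I rate of ~0.052 instead of 0.050.

The brute-force baseline sweeps a fixed threshold Th over [0.05, 1] in
steps of 0.01, rejecting inputs with ℍn > Th, and keeps the Th maximizing
the uncertainty accuracy UA on a validation set (ties → smallest Th).

## Evaluation criteria

With the four-way counts (correct/incorrect × certain/uncertain):
Rc = (Ncc+Nic)/N (coverage), Rcc = Ncc/(Ncc+Nic) (accuracy on accepted),
Rcu = Ncu/(Ncu+Niu) (accuracy on rejected), UA = (Ncc+Niu)/N. Rcc and Rcu
are reported as undefined (None), never as zero, when their denominators
vanish. Two identities hold exactly and are enforced:
accuracy = Rc·Rcc + (1−Rc)·Rcu and UA = Rc·Rcc + (1−Rc)(1−Rcu).

The repeated-holdout protocol splits the training trials into train and
validation portions per repetition (16 by default), stratified by class at
the *trial* level — overlapping crops of one trial are near-duplicates, so
crop-level splitting would leak. The test set never enters training or
validation, and disjointness is machine-checked each run. Accuracy is
crop-wise by default; trial-wise reports pool the k = 5 central crops
(positions straddling the middle crop, biased one left for even counts)
and average their predictions.

## Synthetic data

`generate_eeg` emulates the decoding-relevant physiology only: each
channel carries broadband background noise (white + 1/f, equal power,
scaled by `background_noise_sd`) plus unit-variance band-limited mu and
beta oscillations (amplitudes 2.0 and 1.0). During the MI window
[0.5, 4.5] s the oscillation amplitude on the channels assigned to the
trial's class (deterministic round-robin: channel k ↔ class k mod C) is
multiplied by 1 − erd_depth, with 0.2-s raised-cosine ramps. Defaults — 2
classes, 3 channels, 40 trials per class, erd_depth 0.8, trials spanning
−1.5 to 8.0 s — define the benchmark task used throughout the tests and
the acceptance script. What the simulator does *not* model: volume
conduction and realistic spatial mixing, EOG/EMG artifacts,
nonstationarity across a session, inter-subject variability. Passing tests
therefore demonstrate the machinery is correct and the directional claims
(MOPED convergence, reject-option benefit) hold under clean conditions;
they do not predict absolute accuracies on recorded EEG.

`generate_stacks` draws predictive stacks from a Dirichlet distribution
with mean m (m[true] = 0.7 by default) and concentration parameter
conc·C·m: the single `concentration` knob controls dispersion (σ_d and the
mutual information fall as it grows, while the mean per-row entropy rises
toward ℍ(m) — the Jensen gap ℍ(m) − E[ℍ(row)] *is* the epistemic term).
`deterministic=True` is the infinite-concentration limit.

## Problem sizes and numerical choices

Desk-scale runs (tests and the acceptance script) train on 80 trials (40
per class, 3 channels), 5 crops per trial at a 1-s crop stride, batch 32,
≤ 15 epochs, and evaluate with T = 30 passes on held-out sets with a 0.5-s
crop grid that deliberately includes late, weak-signal crops; these sizes
were chosen so the full suite demonstrates every claim in minutes on one
CPU. Other conventions: logits-stable softmax; safe log via log(x + 1e−6)
inside the network; crop grids computed on integer sample indices to avoid
float drift; all randomness flows from per-call `numpy` generators seeded
explicitly (no global state), and bit-identical repetition under a fixed
seed is asserted for the generators.

## Known limitations

- The adaptive scheme is deliberately conservative: a saturated softmax
  yields M ≈ 1 with tiny σ_d, so well-trained models on easy data reject
  very little. The reject-option tests pool counts over several runs for
  a stable comparison.
- The variational family is fully factorized (mean-field); posterior
  correlations between weights are not captured, and batch-norm parameters
  are treated as point estimates.
- One weight draw is shared across a minibatch (and across inputs within a
  Monte-Carlo pass), which correlates within-pass predictions; passes
  remain independent, which is what the margin test requires.
- No GDF/EDF reader is bundled; recorded data must arrive as array
  containers (HDF5/NPZ) via a user-supplied loader.
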