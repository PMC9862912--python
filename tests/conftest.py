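import numpy as np
import pytest

import bayesmi as bm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_trials():
    """A small 2-class ERD trial set shared by read-only tests."""
    cfg = bm.EEGSimConfig(n_trials_per_class=10, n_classes=2, n_channels=3,
                          erd_depth=0.8, seed=7)
    return bm.generate_eeg(cfg)


@pytest.fixture
def random_stacks(rng):
    """Factory for random Dirichlet predictive stacks."""

    def make(n=50, T=20, C=4, alpha=1.0):
        return rng.dirichlet(np.full(C, alpha), size=(n, T))

    return make


@pytest.fixture(scope="session")
def erd_training_runs():
    """Deterministic, MOPED-prior, and standard-prior models trained on the
    synthetic ERD task (2 classes, erd_depth 0.8, 80 trials) for 3 seeds.

    Shared by the convergence-comparison and reject-option tests so the
    expensive training happens once per session.
    """
    import bayesmi.evaluation as ev

    pre = bm.PreprocessConfig(crop_stride_s=1.0)
    arch = bm.ArchitectureSpec(n_channels=3, n_classes=2)
    tcfg = bm.TrainingConfig(max_epochs=15, patience=6, batch_size=32)
    runs = []
    for seed in (0, 1, 2):
        cfg = bm.EEGSimConfig(n_trials_per_class=40, n_classes=2,
                              n_channels=3, erd_depth=0.8, seed=100 + seed)
        trials = bm.generate_eeg(cfg)
        crops = bm.preprocess(trials, pre)
        plan = bm.ExperimentPlan(val_fraction=0.25, seed=seed)
        tr, va = ev.holdout_split(trials.labels, plan, 0)
        c_tr, c_va = crops.for_trials(tr), crops.for_trials(va)

        det = bm.build_deterministic(arch, seed=seed)
        cfg_s = bm.TrainingConfig(**{**tcfg.__dict__, "seed": seed})
        h_det = bm.train(det, c_tr, c_va, cfg_s)

        moped = bm.to_bayesian(bm.build_deterministic(arch, seed=seed),
                               bm.moped_prior(det.copy_weights()))
        moped.base.set_bn_state(det.bn_state())
        h_moped = bm.train(moped, c_tr, c_va, cfg_s)

        std = bm.to_bayesian(bm.build_deterministic(arch, seed=seed),
                             bm.PriorSpec(kind="standard"))
        h_std = bm.train(std, c_tr, c_va, cfg_s)

        runs.append({"seed": seed, "arch": arch, "pre": pre,
                     "det": det, "moped": moped, "std": std,
                     "hist_det": h_det, "hist_moped": h_moped,
                     "hist_std": h_std})
    return runs


@pytest.fixture(scope="session")
def tiny_arch():
    """A reduced architecture for fast gradient/training unit tests."""
    return bm.ArchitectureSpec(n_channels=2, n_classes=3, input_len=120,
                               temporal_filter_len=9, n_filters=5,
                               avg_pool_len=7, max_pool_len=4,
                               max_pool_stride=4)
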