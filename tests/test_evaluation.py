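"""Reject-option metrics, holdout protocol, crop-position analysis."""

import numpy as np
import pytest

import bayesmi as bm
from bayesmi.evaluation import RejectCounts, central_crop_positions


def counts_oracle(correct, certain):
    cc = ic = cu = iu = 0
    for co, ce in zip(correct, certain):
        if co and ce:
            cc += 1
        elif ce:
            ic += 1
        elif co:
            cu += 1
        else:
            iu += 1
    return cc, ic, cu, iu


class TestCategorize:
    def test_one_of_each(self):
        c = bm.categorize([True, True, False, False],
                          [True, False, True, False])
        assert (c.n_cc, c.n_cu, c.n_ic, c.n_iu) == (1, 1, 1, 1)

    def test_all_correct_certain(self):
        c = bm.categorize(np.ones(7, bool), np.ones(7, bool))
        assert c.n_cc == 7 and c.n_ic == c.n_cu == c.n_iu == 0

    def test_counting_oracle(self, rng):
        correct = rng.uniform(size=1000) < 0.6
        certain = rng.uniform(size=1000) < 0.8
        c = bm.categorize(correct, certain)
        assert (c.n_cc, c.n_ic, c.n_cu, c.n_iu) == \
            tuple(np.array(counts_oracle(correct, certain))[[0, 1, 2, 3]])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bm.categorize([True], [True, False])


class TestRejectMetrics:
    def test_worked_example(self):
        m = bm.reject_metrics(RejectCounts(80, 10, 5, 5))
        assert m.rc == pytest.approx(0.90)
        assert m.rcc == pytest.approx(80 / 90)
        assert m.rcu == pytest.approx(0.50)
        assert m.ua == pytest.approx(0.85)
        assert m.accuracy == pytest.approx(0.85)

    def test_perfect_uncertainty_estimation(self):
        m = bm.reject_metrics(RejectCounts(60, 0, 0, 40))
        assert m.ua == 1.0

    def test_zero_denominators_flagged_not_zero(self):
        m = bm.reject_metrics(RejectCounts(5, 5, 0, 0))
        assert m.rcu is None and m.rcc is not None
        m = bm.reject_metrics(RejectCounts(0, 0, 5, 5))
        assert m.rcc is None
        with pytest.raises(ValueError):
            bm.reject_metrics(RejectCounts(0, 0, 0, 0))

    def test_identities_on_random_counts(self, rng):
        """UA = Rc*Rcc + (1-Rc)(1-Rcu) and accuracy = Rc*Rcc + (1-Rc)*Rcu."""
        for _ in range(300):
            cc, ic, cu, iu = (int(v) for v in rng.integers(1, 200, 4))
            m = bm.reject_metrics(RejectCounts(cc, ic, cu, iu))
            ua = m.rc * m.rcc + (1 - m.rc) * (1 - m.rcu)
            acc = m.rc * m.rcc + (1 - m.rc) * m.rcu
            assert m.ua == pytest.approx(ua, abs=1e-12)
            assert m.accuracy == pytest.approx(acc, abs=1e-12)

    def test_random_guessing_floor(self, rng):
        """Uniform 4-class guessing on balanced labels gives ~25%."""
        n = 20000
        labels = rng.integers(0, 4, n)
        preds = rng.integers(0, 4, n)
        acc = (labels == preds).mean()
        assert abs(acc - 0.25) < 3 * np.sqrt(0.25 * 0.75 / n)


class TestHoldoutSplit:
    def test_stratified_counts(self):
        labels = np.repeat(np.arange(4), 25)
        plan = bm.ExperimentPlan(val_fraction=0.2, seed=1)
        tr, va = bm.holdout_split(labels, plan, 0)
        assert len(va) == 20
        _, counts = np.unique(labels[va], return_counts=True)
        assert np.all(counts == 5)

    def test_deterministic_and_disjoint(self):
        labels = np.repeat([0, 1], 20)
        plan = bm.ExperimentPlan(val_fraction=0.25, seed=3)
        a = bm.holdout_split(labels, plan, 2)
        b = bm.holdout_split(labels, plan, 2)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])
        assert len(np.intersect1d(a[0], a[1])) == 0
        assert len(a[0]) + len(a[1]) == len(labels)
        c = bm.holdout_split(labels, plan, 3)
        assert not np.array_equal(a[1], c[1])

    def test_no_crop_level_leakage(self, small_trials):
        """Every crop of a trial lands on the same side of the split."""
        cfg = bm.PreprocessConfig(crop_stride_s=1.0)
        crops = bm.crop(small_trials, cfg)
        plan = bm.ExperimentPlan(val_fraction=0.2, seed=0)
        tr, va = bm.holdout_split(small_trials.labels, plan, 0)
        tr_crops = crops.for_trials(tr)
        va_crops = crops.for_trials(va)
        assert not set(tr_crops.trial_index) & set(va_crops.trial_index)
        assert tr_crops.n_crops + va_crops.n_crops == crops.n_crops

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            bm.holdout_split(np.array([0, 1]),
                             bm.ExperimentPlan(val_fraction=0.9), 0)


class TestCropProfile:
    def test_flat_stacks_give_flat_profile(self):
        hn = np.full(30, 0.4)
        pos = np.tile(np.arange(10), 3)
        profile = bm.crop_uncertainty_profile(hn, pos)
        np.testing.assert_allclose(profile, 0.4)
        assert len(profile) == 10

    def test_profile_length_matches_crop_grid(self, small_trials):
        crops = bm.crop(small_trials, bm.PreprocessConfig())
        hn = np.zeros(crops.n_crops)
        profile = bm.crop_uncertainty_profile(hn, crops.crop_position)
        assert len(profile) == 563

    def test_ragged_positions_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            bm.crop_uncertainty_profile(np.zeros(5),
                                        np.array([0, 0, 1, 1, 1]))


class TestCentralCrops:
    def test_default_563_selection(self):
        """Five central crops of the 563-crop grid: 0-based positions
        279..283, start times 1.732..1.764 s."""
        sel = central_crop_positions(563, k=5)
        np.testing.assert_array_equal(sel, [279, 280, 281, 282, 283])
        starts = -0.5 + sel * 0.008
        assert starts[0] == pytest.approx(1.732)
        assert starts[-1] == pytest.approx(1.764)

    def test_k_equals_all_is_whole_trial_average(self, rng):
        stacks = rng.dirichlet(np.ones(3), size=(9, 10))
        pos = np.arange(9)
        y_star, c, pooled = bm.central_crop_predict(stacks, pos, k=9)
        np.testing.assert_allclose(y_star, stacks.mean(axis=(0, 1)),
                                   atol=1e-12)
        assert pooled.shape == (90, 3)

    def test_k_too_large_rejected(self, rng):
        stacks = rng.dirichlet(np.ones(3), size=(4, 5))
        with pytest.raises(ValueError):
            bm.central_crop_predict(stacks, np.arange(4), k=6)

    def test_confident_central_crops_decide_trial(self):
        stacks = np.tile([0.1, 0.8, 0.1], (7, 6, 1))
        _, c, pooled = bm.central_crop_predict(stacks, np.arange(7), k=5)
        assert c == 1
        s = bm.summarize(pooled)
        assert bm.decide(s, bm.ThresholdConfig())
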