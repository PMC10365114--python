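"""Tests of the adversarial loops: selection, ascent, synthesis, updates,
and the frozen-generator / clipping / label-conservation guarantees."""

import dataclasses

import numpy as np
import pytest

from cfaug import adversarial as adv
from cfaug import models as md
from cfaug import toyworld as tw
from conftest import clone


def _fake_samples(losses):
    return [tw.ImageSample(np.zeros((2, 2)), 70.0, 0, None, "train", i)
            for i in range(len(losses))]


class _FixedLossClassifier:
    """Classifier stub returning hand-set per-sample losses."""

    def __init__(self, losses):
        self.losses = np.asarray(losses, dtype=float)

    def per_sample_loss(self, images, labels):
        return self.losses[: len(images)]

    def predict_proba(self, images):
        return np.full(len(images), 0.5)


class TestSelectHardSamples:
    def test_highest_losses_selected(self):
        samples = _fake_samples([0.1, 0.9, 0.3, 0.9, 0.2])
        chosen = adv.select_hard_samples(
            _FixedLossClassifier([0.1, 0.9, 0.3, 0.9, 0.2]), samples, 2)
        assert sorted(s.sample_id for s in chosen) == [1, 3]

    def test_full_split(self):
        samples = _fake_samples([0.5, 0.4, 0.3])
        chosen = adv.select_hard_samples(_FixedLossClassifier([0.5, 0.4, 0.3]),
                                         samples, 3)
        assert len(chosen) == 3

    def test_tie_break_by_sample_id(self):
        samples = _fake_samples([0.7] * 5)
        chosen = adv.select_hard_samples(_FixedLossClassifier([0.7] * 5),
                                         samples, 3)
        assert [s.sample_id for s in chosen] == [0, 1, 2]

    def test_min_selected_ge_max_unselected(self, pretrained, balanced_ds):
        train = balanced_ds.split("train")
        losses = md.per_sample_errors(pretrained, train)
        chosen = adv.select_hard_samples(pretrained, train, 20)
        ids = {s.sample_id for s in chosen}
        sel = [l for s, l in zip(train, losses) if s.sample_id in ids]
        uns = [l for s, l in zip(train, losses) if s.sample_id not in ids]
        assert min(sel) >= max(uns)

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError):
            adv.select_hard_samples(_FixedLossClassifier([0.1]),
                                    _fake_samples([0.1]), 2)


class TestInitTargetAges:
    def test_real_age_mode(self, balanced_ds):
        hard = balanced_ds.split("train")[:10]
        a = adv.init_target_ages(hard, "real_age", seed=0)
        assert np.array_equal(a, tw.ages_of(hard))

    def test_degenerate_interval_at_max_age(self):
        s = tw.ImageSample(np.zeros((2, 2)), 90.0, 0, None, "train", 0)
        a = adv.init_target_ages([s], "uniform_to_max", seed=1)
        assert a[0] == pytest.approx(90.0)

    def test_uniform_mean(self):
        samples = [tw.ImageSample(np.zeros((2, 2)), 60.0, 0, None, "train", i)
                   for i in range(10000)]
        a = adv.init_target_ages(samples, "uniform_to_max", seed=2)
        assert abs(a.mean() - 75.0) < 0.5
        assert a.min() >= 60.0 and a.max() <= 90.0


class _SurrogatePair:
    """G/C pair with closed-form per-sample loss L_i(a) = -(a_i - 80)^2.

    The 'image' for sample i is the scalar a_i broadcast to one pixel, so
    dL/da = dL/dimg * dimg/da with dimg/da = 1.
    """

    class G:
        def generate_with_age_grad(self, samples, ages):
            imgs = np.asarray(ages, dtype=float).reshape(-1, 1, 1)
            return imgs, np.ones_like(imgs)

        def generate(self, samples, ages):
            return np.asarray(ages, dtype=float).reshape(-1, 1, 1)

    class C:
        def input_gradient(self, images, labels):
            return -2.0 * (images - 80.0)

        def per_sample_loss(self, images, labels):
            return -((images[:, 0, 0] - 80.0) ** 2)


class TestAscendTargetAges:
    def test_zero_gradient_leaves_ages_unchanged(self, balanced_ds, oracle):
        hard = balanced_ds.split("train")[:5]

        class ConstantC:
            def input_gradient(self, images, labels):
                return np.zeros_like(images)

        cfg = adv.AugmentConfig(n_hard=5, seed=0)
        a = tw.ages_of(hard)
        out = adv.ascend_target_ages(a.copy(), hard, oracle, ConstantC(), cfg)
        assert np.array_equal(out, a)

    def test_closed_form_surrogate_step(self):
        pair = _SurrogatePair()
        hard = _fake_samples([0.0])
        cfg = adv.AugmentConfig(n_hard=1, gamma_a=0.1, n_ascent=1, seed=0)
        out = adv.ascend_target_ages(np.array([70.0]), hard, pair.G(), pair.C(), cfg)
        # dL/da at 70 = -2*(70-80) = 20; step = gamma_a * 20
        assert out[0] == pytest.approx(70.0 + 0.1 * 20.0)

    def test_clipping_at_upper_bound(self):
        class UpC:  # constant positive gradient pushes ages past the bound
            def input_gradient(self, images, labels):
                return np.ones_like(images)

        pair = _SurrogatePair()
        hard = _fake_samples([0.0])
        cfg = adv.AugmentConfig(n_hard=1, gamma_a=10.0, n_ascent=1, seed=0)
        out = adv.ascend_target_ages(np.array([89.95]), hard, pair.G(), UpC(), cfg)
        assert out[0] == 90.0

    def test_nonfinite_gradient_aborts(self):
        class NanC:
            def input_gradient(self, images, labels):
                return np.full_like(images, np.nan)

        pair = _SurrogatePair()
        cfg = adv.AugmentConfig(n_hard=1, seed=0)
        with pytest.raises(FloatingPointError):
            adv.ascend_target_ages(np.array([70.0]), _fake_samples([0.0]),
                                   pair.G(), NanC(), cfg)

    def test_first_order_ascent_increases_loss(self, balanced_ds, oracle, pretrained):
        """Predicted first-order change gamma*||grad||^2 >= 0 and the
        realized hard-set loss increases for a small enough step."""
        hard = adv.select_hard_samples(pretrained, balanced_ds.split("train"), 20)
        labels = tw.labels_of(hard)
        a = tw.ages_of(hard)
        for gamma in (50.0, 5.0):
            cfg = adv.AugmentConfig(n_hard=20, gamma_a=gamma, n_ascent=1, seed=0)
            before = pretrained.per_sample_loss(oracle.generate(hard, a), labels).mean()
            out = adv.ascend_target_ages(a.copy(), hard, oracle, pretrained, cfg)
            after = pretrained.per_sample_loss(oracle.generate(hard, out), labels).mean()
            if after > before:
                break
        assert after > before


class TestSynthesize:
    def test_labels_and_cardinality(self, balanced_ds, oracle):
        hard = balanced_ds.split("train")[:7]
        a = np.linspace(60, 90, 7)
        syn = adv.synthesize_counterfactuals(hard, a, oracle)
        assert len(syn) == 7
        assert [s.diagnosis for s in syn] == [s.diagnosis for s in hard]
        assert [s.age for s in syn] == list(a)

    def test_real_age_gives_noiseless_rerender(self, balanced_ds, oracle):
        hard = balanced_ds.split("train")[:3]
        syn = adv.synthesize_counterfactuals(hard, tw.ages_of(hard), oracle)
        for s, orig in zip(syn, hard):
            expect = tw.render(orig.subject, orig.age, orig.diagnosis,
                               orig.image.shape[0],
                               render_cfg=balanced_ds.render_config)
            assert np.allclose(s.image, expect)

    def test_misaligned_ages_rejected(self, balanced_ds, oracle):
        with pytest.raises(ValueError):
            adv.synthesize_counterfactuals(balanced_ds.split("train")[:3],
                                           np.array([70.0]), oracle)


class TestClassifierUpdate:
    def test_combined_epoch_count(self, pretrained, balanced_ds, oracle, rng):
        clf = clone(pretrained)
        train = balanced_ds.split("train")
        syn = adv.synthesize_counterfactuals(train[:10], tw.ages_of(train[:10]),
                                             oracle)
        cfg = adv.AugmentConfig(n_hard=10, seed=0)
        loss = adv.classifier_update(clf, train, syn, cfg, rng)
        assert np.isfinite(loss)

    def test_empty_synthetic_is_plain_epoch(self, pretrained, balanced_ds, rng):
        clf = clone(pretrained)
        cfg = adv.AugmentConfig(n_hard=10, seed=0)
        loss = adv.classifier_update(clf, balanced_ds.split("train"), [], cfg, rng)
        assert np.isfinite(loss)

    def test_synthetic_loss_decreases_most_seeds(self, pretrained, balanced_ds, oracle):
        wins = 0
        train = balanced_ds.split("train")
        for seed in range(5):
            clf = clone(pretrained)
            rng = np.random.default_rng(seed)
            hard = adv.select_hard_samples(clf, train, 30)
            ages = adv.init_target_ages(hard, "uniform_to_max", seed)
            syn = adv.synthesize_counterfactuals(hard, ages, oracle)
            cfg = adv.AugmentConfig(n_hard=30, classifier_lr=1e-4, seed=seed)
            before = md.per_sample_errors(clf, syn).mean()
            adv.classifier_update(clf, train, syn, cfg, rng)
            after = md.per_sample_errors(clf, syn).mean()
            wins += after < before
        assert wins >= 4


class TestAdversarialAugment:
    def test_k_zero_leaves_classifier_unchanged(self, pretrained, balanced_ds, oracle):
        clf = clone(pretrained)
        cfg = adv.AugmentConfig(n_hard=20, k=0, seed=0)
        out, hist = adv.adversarial_augment(clf, oracle, balanced_ds, cfg)
        assert len(hist) == 0
        for a, b in zip(out.parameter_snapshot(), pretrained.parameter_snapshot()):
            assert np.array_equal(a, b)

    def test_history_length_and_clip_invariant(self, pretrained, balanced_ds, oracle):
        clf = clone(pretrained)
        cfg = adv.AugmentConfig(n_hard=20, k=4, seed=1)
        _, hist = adv.adversarial_augment(clf, oracle, balanced_ds, cfg)
        assert len(hist) == 4
        snaps = hist.age_snapshots()
        assert snaps.min() >= 60.0 and snaps.max() <= 90.0

    def test_label_conservation_every_iteration(self, pretrained, balanced_ds, oracle):
        """The synthetic multiset of labels equals the hard set's at every
        iteration (the hard set is fixed, ages never touch the labels)."""
        clf = clone(pretrained)
        cfg = adv.AugmentConfig(n_hard=25, k=3, seed=2)
        _, hist = adv.adversarial_augment(clf, oracle, balanced_ds, cfg)
        labels = hist.hard_labels()
        for rec in hist.records:
            assert len(rec["target_ages"]) == 25
        hard = adv.select_hard_samples(pretrained, balanced_ds.split("train"), 25)
        assert sorted(labels) == sorted(tw.labels_of(hard))

    def test_generator_frozen(self, pretrained, balanced_ds, neural_gen):
        clf = clone(pretrained)
        before = neural_gen.parameter_snapshot()
        cfg = adv.AugmentConfig(n_hard=10, k=2, seed=0)
        adv.adversarial_augment(clf, neural_gen, balanced_ds, cfg)
        for a, b in zip(before, neural_gen.parameter_snapshot()):
            assert np.array_equal(a, b)


class TestContinual:
    def test_m100_identical_to_plain_loop(self, pretrained, balanced_ds, oracle):
        cfg = adv.AugmentConfig(n_hard=20, k=3, seed=5, memory_fraction=100.0)
        c1, h1 = adv.adversarial_augment(clone(pretrained), oracle, balanced_ds, cfg)
        c2, h2 = adv.continual_adversarial_augment(clone(pretrained), oracle,
                                                   balanced_ds, cfg)
        assert np.array_equal(h1.age_snapshots(), h2.age_snapshots())
        for a, b in zip(c1.parameter_snapshot(), c2.parameter_snapshot()):
            assert np.array_equal(a, b)

    def test_store_size(self, pretrained, balanced_ds, oracle):
        cfg = adv.AugmentConfig(n_hard=10, k=1, seed=0, memory_fraction=20.0)
        _, hist = adv.continual_adversarial_augment(clone(pretrained), oracle,
                                                    balanced_ds, cfg)
        n_train = len(balanced_ds.split("train"))
        assert hist.sub_seeds["store_size"] == round(0.2 * n_train)

    def test_small_buffer_clamps_n_hard_with_warning(self, pretrained,
                                                     balanced_ds, oracle):
        cfg = adv.AugmentConfig(n_hard=100, k=1, seed=0, memory_fraction=5.0)
        with pytest.warns(UserWarning, match="lowering n_hard"):
            _, hist = adv.continual_adversarial_augment(clone(pretrained), oracle,
                                                        balanced_ds, cfg)
        assert len(hist.records[0]["target_ages"]) == hist.sub_seeds["store_size"]


class TestGeneratorVsClassifier:
    def test_oracle_rejected(self, pretrained, balanced_ds, oracle):
        cfg = adv.AugmentConfig(seed=0)
        with pytest.raises(TypeError):
            adv.train_generator_adversarially(oracle, clone(pretrained),
                                              balanced_ds, cfg)

    def test_both_players_change(self, pretrained, balanced_ds, neural_gen):
        G = clone(neural_gen)
        C = clone(pretrained)
        g0, c0 = G.parameter_snapshot(), C.parameter_snapshot()
        cfg = adv.AugmentConfig(seed=0, gvc_epochs=2, gvc_n_syn=30)
        adv.train_generator_adversarially(G, C, balanced_ds, cfg)
        assert any(not np.array_equal(a, b)
                   for a, b in zip(g0, G.parameter_snapshot()))
        assert any(not np.array_equal(a, b)
                   for a, b in zip(c0, C.parameter_snapshot()))


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"gamma_a": 0.0}, {"k": -1}, {"clip_range": (90.0, 60.0)},
        {"memory_fraction": 0.0}, {"memory_fraction": 101.0},
        {"init_mode": "bogus"}, {"selection": "bogus"},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            adv.AugmentConfig(**kw)
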