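import numpy as np
import pytest

from wriststep.classifier import (ClassifierConfig, EarlyStopper, EpochDataset,
                                  augment_window, class_weights,
                                  predict_epochs, train_classifier,
                                  _rotation_matrix)
from wriststep.io import NONWALK, WALK
from wriststep.metrics import classification_metrics


def _separable_dataset(n_walk, n_nonwalk, seed, fs=25.0, n_per=250):
    """High-variance periodic walk epochs vs near-flat non-walk epochs."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_per) / fs
    wins, labels = [], []
    for _ in range(n_walk):
        f = rng.uniform(1.5, 2.2)
        amp = rng.uniform(0.4, 0.7)
        sig = amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        w = np.column_stack([sig, np.zeros(n_per), np.ones(n_per)])
        wins.append(w + rng.normal(0, 0.02, (n_per, 3)))
        labels.append(WALK)
    for _ in range(n_nonwalk):
        w = np.column_stack([np.zeros(n_per), np.zeros(n_per), np.ones(n_per)])
        wins.append(w + rng.normal(0, 0.02, (n_per, 3)))
        labels.append(NONWALK)
    order = rng.permutation(len(labels))
    return EpochDataset(np.stack(wins)[order], np.array(labels)[order], fs,
                        np.array(["p"] * len(labels)))


class TestAugmentation:
    def test_zero_angle_identity_permutation_is_noop(self, rng):
        w = rng.normal(size=(100, 3))
        R = _rotation_matrix(np.array([0.0, 0.0, 1.0]), 0.0)
        np.testing.assert_allclose(w @ R.T, w, atol=1e-12)

    def test_magnitude_preserved(self, rng):
        w = rng.normal(size=(250, 3))
        out = augment_window(w, rng)
        np.testing.assert_allclose(np.linalg.norm(out, axis=1),
                                   np.linalg.norm(w, axis=1), atol=1e-9)

    def test_fixed_seed_reproducible(self):
        w = np.random.default_rng(0).normal(size=(50, 3))
        a = augment_window(w, np.random.default_rng(7))
        b = augment_window(w, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)


class TestClassWeights:
    def test_matching_balance_gives_unit_weights(self):
        labels = np.array([WALK] * 10 + [NONWALK] * 90)
        assert class_weights(labels) == pytest.approx((1.0, 1.0))

    def test_even_balance_rebalanced_to_10_90(self):
        labels = np.array([WALK] * 50 + [NONWALK] * 50)
        w_walk, w_nonwalk = class_weights(labels)
        mass_walk = w_walk * 50
        mass_nonwalk = w_nonwalk * 50
        assert mass_walk / (mass_walk + mass_nonwalk) == pytest.approx(0.10)

    def test_absent_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            class_weights(np.array([WALK, WALK]))


class TestEarlyStopping:
    def test_monotone_increase_stops_after_patience(self):
        s = EarlyStopper(patience=5)
        losses = [1.0, 1.1, 1.2, 1.3, 1.4, 1.5, 1.6]
        stopped_at = None
        for i, l in enumerate(losses):
            if s.update(l, i):
                stopped_at = i
                break
        assert stopped_at == 5          # six epochs run: 0..5
        assert s.best_epoch == 0        # epoch-1 parameters (index 0) kept

    def test_ties_count_as_not_decreasing(self):
        s = EarlyStopper(patience=2)
        assert not s.update(1.0, 0)
        assert not s.update(1.0, 1)
        assert s.update(1.0, 2)
        assert s.best_epoch == 0


class TestTraining:
    def test_separable_data_reaches_perfect_training_accuracy(self):
        train = _separable_dataset(60, 240, seed=0)
        val = _separable_dataset(15, 60, seed=1)
        model = train_classifier(train, val, ClassifierConfig(seed=3))
        p = model.predict_proba(train.windows)
        acc = np.mean((p >= 0.5) == (train.labels == WALK))
        assert acc == 1.0

    def test_heldout_kappa_high_on_separable_data(self):
        train = _separable_dataset(60, 240, seed=0)
        val = _separable_dataset(15, 60, seed=1)
        test = _separable_dataset(30, 120, seed=2)
        model = train_classifier(train, val, ClassifierConfig(seed=3))
        p = model.predict_proba(test.windows)
        pred = np.where(p >= 0.5, WALK, NONWALK)
        assert classification_metrics(test.labels, pred).kappa >= 0.9

    def test_early_stopping_never_returns_later_than_best(self):
        train = _separable_dataset(40, 160, seed=4)
        val = _separable_dataset(10, 40, seed=5)
        model = train_classifier(train, val,
                                 ClassifierConfig(seed=6, max_train_epochs=40))
        val_losses = [h["val_loss"] for h in model.history]
        assert model.best_epoch == int(np.argmin(val_losses))
        assert len(model.history) <= model.best_epoch + 1 + 5  # patience bound

    def test_single_class_training_errors(self):
        ds = _separable_dataset(10, 40, seed=0)
        only_walk = EpochDataset(ds.windows[ds.labels == WALK],
                                 ds.labels[ds.labels == WALK],
                                 ds.sample_rate, ds.participant[:10])
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(only_walk, ds, ClassifierConfig())

    def test_default_learning_rate_is_adam_paper_value(self):
        assert ClassifierConfig().learning_rate == pytest.approx(1e-4)

    def test_prediction_deterministic(self):
        train = _separable_dataset(30, 120, seed=0)
        val = _separable_dataset(10, 40, seed=1)
        model = train_classifier(train, val,
                                 ClassifierConfig(seed=2, max_train_epochs=20))
        p1 = model.predict_proba(val.windows)
        p2 = model.predict_proba(val.windows)
        np.testing.assert_array_equal(p1, p2)


class TestPrediction:
    def test_rate_mismatch_errors(self, clean_walk_recording):
        rec, _, epochs = clean_walk_recording
        train = _separable_dataset(20, 80, seed=0, fs=25.0)
        val = _separable_dataset(10, 40, seed=1, fs=25.0)
        model = train_classifier(train, val,
                                 ClassifierConfig(seed=0, max_train_epochs=5))
        with pytest.raises(ValueError, match="sample-rate mismatch"):
            predict_epochs(model, rec, epochs)  # recording is 100 Hz

    def test_invalid_epochs_stay_unknown(self):
        from wriststep.io import window_epochs
        from wriststep.simulate import GaitScenario, simulate_recording
        sc = GaitScenario(duration=60.0, bouts=[],
                          nonwear_gaps=[(10.0, 20.0)], seed=0,
                          sample_rate=25.0)
        rec, _, _ = simulate_recording(sc)
        epochs = window_epochs(rec, 10.0)
        train = _separable_dataset(20, 80, seed=0, fs=25.0)
        val = _separable_dataset(10, 40, seed=1, fs=25.0)
        model = train_classifier(train, val,
                                 ClassifierConfig(seed=0, max_train_epochs=5))
        prob, labels = predict_epochs(model, rec, epochs)
        assert labels[1] == -1 and np.isnan(prob[1])
        assert (labels[[0, 2]] != -1).all()


def test_augmented_mlp_is_more_rotation_invariant():
    """Rotation robustness of the raw-signal net improves with augmentation."""
    train = _separable_dataset(80, 240, seed=0)
    val = _separable_dataset(20, 60, seed=1)
    test = _separable_dataset(40, 120, seed=2)
    rot_rng = np.random.default_rng(99)
    rotated = np.stack([augment_window(w, rot_rng) for w in test.windows])

    diffs = {}
    for aug in (True, False):
        cfg = ClassifierConfig(backend="mlp_raw", augment=aug, seed=5,
                               max_train_epochs=60, learning_rate=1e-3)
        model = train_classifier(train, val, cfg)
        p0 = model.predict_proba(test.windows)
        p1 = model.predict_proba(rotated)
        diffs[aug] = np.mean(np.abs(p0 - p1))
    assert diffs[True] < diffs[False]
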