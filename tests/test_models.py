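"""Model construction, training and inference contracts.

Training tests run on short 100-sample windows (the architecture's
conv/pool chain admits any window of at least ~76 samples), keeping them
fast while exercising the identical code paths as full 600-sample windows.
"""

import dataclasses

import numpy as np
import pytest

from mindfuse import models, nn
from mindfuse.io_formats import Session
from mindfuse.preprocessing import Segment

WINDOW = 100


def toy_segments(rng, n_per_class=24, subject="s0", separation=3.0,
                 window=WINDOW):
    """Two classes separated by the variance of one channel group."""
    segs = []
    for label in (0, 1):
        scale = 1.0 if label else separation
        sess = Session.ADAS if label else Session.MANUAL1
        for _ in range(n_per_class):
            data = rng.standard_normal((window, 8))
            data[:, :6] *= scale
            segs.append(Segment(data=data, label=label, subject_id=subject,
                                session=sess))
    return segs


class TestBuild:
    def test_sensor_config_controls_input_channels(self):
        for sensors, n in (("eeg", 6), ("eeg+spr", 7), ("eeg+ecg", 7),
                           ("eeg+spr+ecg", 8)):
            spec = models.ModelSpec(arch="data_fusion", sensors=sensors)
            assert spec.n_input_channels == n
            handle = models.build(spec)
            assert len(handle.channel_idx) == n

    def test_feature_fusion_spatial_conv_only_in_eeg_branch(self):
        handle = models.build(models.ModelSpec(arch="feature_fusion",
                                               sensors="eeg+spr+ecg"))
        convs_per_branch = [
            sum(e["layer"].startswith("conv") for e in b.inventory())
            for b in handle.net.branches]
        assert convs_per_branch == [5, 4, 4]

    def test_window_too_short_raises_architecture_error(self):
        with pytest.raises(nn.ArchitectureError):
            models.build(models.ModelSpec(arch="data_fusion",
                                          window_samples=40))

    def test_min_window_admits_four_blocks(self):
        w = models.min_window_samples()
        assert models.time_after_blocks(w) >= 1
        with pytest.raises(nn.ArchitectureError):
            models.time_after_blocks(w - 1)

    def test_arch_defaults_differ(self):
        data = models.ModelSpec(arch="data_fusion")
        feat = models.ModelSpec(arch="feature_fusion")
        assert (data.dropout, data.l2_penalty) == (0.38, 1.3)
        assert (feat.dropout, feat.l2_penalty) == (0.5, 0.7)
        assert (data.max_epochs, data.early_stopping_patience) == (200, 50)
        assert (feat.max_epochs, feat.early_stopping_patience) == (50, 20)

    def test_single_dense_layer_parameter_count(self):
        rng = np.random.default_rng(0)
        assert nn.Dense(10, 2, rng).param_count == 22

    def test_dropping_hidden_dense_shrinks_below_branch_sum(self):
        """The 500-unit dense layer holds most of the fusion network's
        capacity: without it the parameter count falls below the combined
        size of the data-level net and the three branches."""
        full = models.count_trainable_parameters(models.build(
            models.ModelSpec(arch="feature_fusion", sensors="eeg+spr+ecg")))
        ablated = models.count_trainable_parameters(models.build(
            models.ModelSpec(arch="feature_fusion", sensors="eeg+spr+ecg",
                             dense_hidden=0)))
        data_level = models.count_trainable_parameters(models.build(
            models.ModelSpec(arch="data_fusion", sensors="eeg+spr+ecg")))
        branches_sum = full - ablated  # dense capacity removed
        assert ablated < data_level + branches_sum
        assert ablated < full


@pytest.fixture(scope="module")
def trained():
    rng = np.random.default_rng(0)
    train = toy_segments(rng, n_per_class=48, subject="a")
    spec = models.ModelSpec(arch="data_fusion", sensors="eeg+spr+ecg",
                            window_samples=WINDOW, max_epochs=8,
                            early_stopping_patience=8,
                            learning_rate=3e-3, seed=0)
    handle = models.train(models.build(spec), train, spec)
    return handle, train, rng


class TestTrainPredict:
    def test_learns_separable_classes(self, trained):
        handle, train, rng = trained
        test = toy_segments(rng, n_per_class=24, subject="b")
        labels, _ = models.predict(handle, test)
        truth = np.array([s.label for s in test])
        assert (labels == truth).mean() > 0.9

    def test_probabilities_normalized_and_deterministic(self, trained):
        handle, train, rng = trained
        seg = train[0]
        labels, probs = models.predict(handle, [seg, seg])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all() and (probs <= 1).all()
        np.testing.assert_array_equal(probs[0], probs[1])
        assert labels[0] == labels[1]

    def test_same_seed_reproduces_training_exactly(self):
        rng = np.random.default_rng(3)
        train = toy_segments(rng, n_per_class=24)
        losses = []
        for _ in range(2):
            spec = models.ModelSpec(arch="feature_fusion",
                                    sensors="eeg+spr+ecg",
                                    window_samples=WINDOW, max_epochs=2,
                                    early_stopping_patience=2, seed=11)
            handle = models.train(models.build(spec), train, spec)
            losses.append(handle.history["train_loss"])
        assert losses[0] == losses[1]

    def test_single_class_training_set_rejected(self):
        rng = np.random.default_rng(4)
        segs = [s for s in toy_segments(rng) if s.label == 0]
        spec = models.ModelSpec(arch="data_fusion",
                                window_samples=WINDOW)
        with pytest.raises(models.TrainingError):
            models.train(models.build(spec), segs, spec)

    def test_permuted_labels_stay_near_chance(self):
        rng = np.random.default_rng(5)
        train = toy_segments(rng, n_per_class=48, subject="a")
        perm = rng.permutation([s.label for s in train])
        shuffled = [dataclasses.replace(s, label=int(l))
                    for s, l in zip(train, perm)]
        # keep both classes present after permutation
        spec = models.ModelSpec(arch="data_fusion", sensors="eeg+spr+ecg",
                                window_samples=WINDOW, max_epochs=4,
                                early_stopping_patience=4, seed=1)
        handle = models.train(models.build(spec), shuffled, spec)
        held_out = toy_segments(rng, n_per_class=40, subject="b")
        labels, _ = models.predict(handle, held_out)
        truth = np.array([s.label for s in held_out])
        assert 0.4 <= (labels == truth).mean() <= 0.6

    def test_checkpoint_round_trip(self, trained, tmp_path):
        handle, train, rng = trained
        path = tmp_path / "model.npz"
        models.save_model(handle, path)
        back = models.load_model(path)
        test = toy_segments(np.random.default_rng(9), n_per_class=8)
        l1, p1 = models.predict(handle, test)
        l2, p2 = models.predict(back, test)
        np.testing.assert_allclose(p1, p2, atol=1e-6)
        sidecar = path.with_suffix(".json")
        assert sidecar.exists()
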