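"""Architecture contracts, clinical encoding, training-loop behaviour."""

import numpy as np
import pytest

from metasurv.models import (ArchitectureConfig, ClinicalDataset, ConvBlock,
                             DESK_BLOCKS_3D, ImageDataset, TrainConfig,
                             build_ann, build_cnn, build_fusion,
                             clinical_vector, clinical_vector_width, predict,
                             train)
from metasurv.nn import Flatten
from metasurv.preprocessing import AugmentConfig, PreprocessConfig
from metasurv.survival import DiscreteTimeGrid, encode_targets

DESK_ARCH = ArchitectureConfig(conv_blocks=DESK_BLOCKS_3D, crop_extent=32,
                               fc_sizes=(16, 8))


class TestArchitectureContracts:
    def test_default_full_scale_flattens_to_128(self):
        """Three default blocks reduce a 128-voxel crop to 128 flat features."""
        arch = ArchitectureConfig()
        net = build_cnn(arch, seed=0)
        shape = (1, arch.crop_extent, arch.crop_extent, arch.crop_extent)
        for layer in net.image_layers:
            shape = layer.output_shape(shape)
        assert shape == (128,)

    def test_time_to_event_head_has_one_unit_per_interval(self):
        net = build_cnn(DESK_ARCH, seed=0)
        x = np.random.default_rng(0).uniform(-1, 1, (2, 1, 32, 32, 32))
        out = net.forward(x_image=x)
        assert out.shape == (2, 10)
        assert np.all((out > 0) & (out < 1))

    def test_binary_head_single_unit(self):
        arch = ArchitectureConfig(conv_blocks=DESK_BLOCKS_3D, crop_extent=32,
                                  fc_sizes=(16, 8), head="binary")
        out = build_cnn(arch, seed=0).forward(
            x_image=np.zeros((3, 1, 32, 32, 32)))
        assert out.shape == (3, 1)
        assert np.all((out > 0) & (out < 1))

    def test_2d_variant(self):
        arch = ArchitectureConfig(dimensionality="2D",
                                  conv_blocks=DESK_BLOCKS_3D, crop_extent=32,
                                  fc_sizes=(16, 8))
        out = build_cnn(arch, seed=0).forward(x_image=np.zeros((2, 1, 32, 32)))
        assert out.shape == (2, 10)

    def test_incompatible_blocks_reported(self):
        bad = ArchitectureConfig(
            conv_blocks=(ConvBlock(8, 3, 1, 3, 3),), crop_extent=32)
        with pytest.raises(ValueError, match="block 0"):
            build_cnn(bad, seed=0)

    def test_blocks_not_reducing_to_one_rejected(self):
        bad = ArchitectureConfig(
            conv_blocks=(ConvBlock(8, 3, 1, 4, 4),), crop_extent=32)
        with pytest.raises(ValueError, match="expected 1"):
            build_cnn(bad, seed=0)

    def test_same_seed_identical_initialisation(self):
        a = build_cnn(DESK_ARCH, seed=3)
        b = build_cnn(DESK_ARCH, seed=3)
        for pa, pb in zip(a.get_weights(), b.get_weights()):
            np.testing.assert_array_equal(pa, pb)


class TestClinicalEncoding:
    def test_width_is_two_continuous_plus_onehots(self, small_cohort):
        _, records = small_cohort
        v = clinical_vector(records[0])
        assert v.shape == (clinical_vector_width(),)
        assert clinical_vector_width() == 2 + 2 + 4 + 4 + 4 + 4

    def test_onehot_blocks_sum_to_one(self, small_cohort):
        _, records = small_cohort
        v = clinical_vector(records[0])
        blocks = [(2, 4), (4, 8), (8, 12), (12, 16), (16, 20)]
        for lo, hi in blocks:
            assert v[lo:hi].sum() == 1.0

    def test_continuous_scaled_by_100(self, small_cohort):
        _, records = small_cohort
        r = records[0]
        v = clinical_vector(r)
        assert v[0] == pytest.approx(r.age_years / 100)
        assert v[1] == pytest.approx(r.gtv_total_volume_cm3 / 100)

    def test_unknown_level_named_in_error(self, small_cohort):
        _, records = small_cohort
        r = records[0]
        bad = type(r)(**{**r.__dict__, "site": "tonsil"})
        with pytest.raises(ValueError, match="tonsil"):
            clinical_vector(bad)


class TestAnnAndFusion:
    def test_ann_hidden_width_14(self):
        net = build_ann()
        assert net.head_layers[0].params[0].shape == (clinical_vector_width(), 14)

    def test_ann_statelessness_under_permutation(self, small_cohort):
        _, records = small_cohort
        net = build_ann(seed=1)
        ds = ClinicalDataset(records)
        out = predict(net, ds)
        perm = np.array([3, 0, 2, 1, 5, 4, 7, 6])
        out_perm = net.forward(x_clinical=ds.clinical[perm])
        np.testing.assert_allclose(out_perm, out[perm], atol=1e-6)

    def test_fusion_concatenates_at_flatten(self):
        net = build_fusion(DESK_ARCH, seed=0)
        assert isinstance(net.image_layers[-1], Flatten)
        first_dense = net.head_layers[0]
        expected_in = DESK_BLOCKS_3D[-1].n_kernels + clinical_vector_width()
        assert first_dense.params[0].shape[0] == expected_in

    def test_constant_image_branch_leaves_clinical_dependence(self, small_cohort):
        _, records = small_cohort
        net = build_fusion(DESK_ARCH, seed=0)
        zeros = np.zeros((2, 1, 32, 32, 32))
        c = np.stack([clinical_vector(records[0]), clinical_vector(records[1])])
        out = net.forward(x_image=zeros, x_clinical=c)
        assert not np.allclose(out[0], out[1])  # differs through clinical input
        same_c = np.stack([c[0], c[0]])
        out2 = net.forward(x_image=zeros, x_clinical=same_c)
        np.testing.assert_allclose(out2[0], out2[1], atol=1e-6)


class TestTraining:
    def _toy_setup(self, n=40, seed=0):
        """Separable toy task: risk increases with a single clinical feature."""
        rng = np.random.default_rng(seed)
        x = rng.uniform(-1, 1, (n, 3)).astype(np.float32)
        labels = (x[:, 0] > 0).astype(float)

        class DS:
            def __init__(self, x):
                self.x = x
            def __len__(self):
                return len(self.x)
            def batch(self, idx, training, rng):
                return {"x_clinical": self.x[idx]}

        from metasurv.nn import Dense, Network, ReLU, Sigmoid
        net = Network(None, [Dense(3, 8, np.random.default_rng(1)), ReLU(),
                             Dense(8, 1, np.random.default_rng(2)), Sigmoid()],
                      clinical_width=3)
        return net, DS(x[:30]), labels[:30], DS(x[30:]), labels[30:]

    def test_loss_decreases_on_separable_task(self):
        net, tr, yl, va, yv = self._toy_setup()
        cfg = TrainConfig(learning_rate=0.01, batch_size=10, epochs=30,
                          early_stopping_patience=30, seed=0)
        hist = train(net, tr, yl, va, yv, cfg, task="binary")
        losses = hist.to_frame()["train_loss"].to_numpy()
        assert losses[5] < losses[0]
        assert losses.min() < 0.5 * losses[0]

    def test_best_checkpoint_is_argmax_of_history(self):
        net, tr, yl, va, yv = self._toy_setup()
        cfg = TrainConfig(learning_rate=0.01, batch_size=10, epochs=20,
                          early_stopping_patience=20, seed=0)
        hist = train(net, tr, yl, va, yv, cfg, task="binary")
        frame = hist.to_frame()
        assert hist.best_metric == frame["val_metric"].max()
        assert hist.best_epoch == int(frame["val_metric"].idxmax())

    def test_early_stopping_stops_after_patience(self):
        net, tr, yl, va, yv = self._toy_setup()
        cfg = TrainConfig(learning_rate=0.01, batch_size=10, epochs=500,
                          early_stopping_patience=5, seed=0)
        hist = train(net, tr, yl, va, yv, cfg, task="binary")
        if hist.stopped_early:
            assert len(hist.epochs) == hist.best_epoch + cfg.early_stopping_patience + 1

    def test_training_deterministic_under_fixed_seed(self):
        results = []
        for _ in range(2):
            net, tr, yl, va, yv = self._toy_setup()
            cfg = TrainConfig(learning_rate=0.01, batch_size=10, epochs=5,
                              early_stopping_patience=5, seed=9)
            hist = train(net, tr, yl, va, yv, cfg, task="binary")
            results.append(hist.to_frame()["train_loss"].to_numpy())
        np.testing.assert_array_equal(results[0], results[1])

    def test_survival_task_improves_concordance(self, medium_cohort):
        """Desk-scale ANN learns a volume-driven hazard above chance."""
        cfg, records = medium_cohort
        times = np.array([r.time_years for r in records])
        events = np.array([r.event for r in records])
        grid = DiscreteTimeGrid()
        ds_tr, ds_va = ClinicalDataset(records[:140]), ClinicalDataset(records[140:])
        tcfg = TrainConfig(learning_rate=1e-2, batch_size=16, epochs=1000,
                           early_stopping_patience=400, seed=0)
        hist = train(build_ann(), ds_tr, (times[:140], events[:140]),
                     ds_va, (times[140:], events[140:]), tcfg,
                     task="time_to_event", grid=grid,
                     targets=encode_targets(events[:140], times[:140], grid))
        assert hist.best_metric > 0.6

    def test_image_dataset_shapes(self, small_cohort):
        _, records = small_cohort
        pre = PreprocessConfig(target_spacing=2.0, input_extent=32, crop_extent=32)
        ds = ImageDataset(records, pre, AugmentConfig(), with_clinical=True)
        batch = ds.batch(np.array([0, 1]), training=False, rng=None)
        assert batch["x_image"].shape == (2, 1, 32, 32, 32)
        assert batch["x_clinical"].shape == (2, clinical_vector_width())
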