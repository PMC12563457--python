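"""Split arithmetic, stratification, and the optimization loops."""

import numpy as np
import pandas as pd
import pytest

from cardiossl.models import build_model, encoder_spec, transfer_surgery
from cardiossl.pretext import LossSpec, make_noise_pretext
from cardiossl.synthetic import ImageSet, NoiseConfig, PhantomConfig, generate_dataset
from cardiossl.training import (SplitPlan, TrainConfig, accuracy,
                                split_dataset, split_sizes, train_downstream,
                                train_pretext)


def _balanced_set(n, seed=0):
    rng = np.random.default_rng(seed)
    images = rng.random((n, 16, 16, 3)).astype(np.float32)
    labels = np.arange(n) % 2
    return ImageSet(images, labels, [f"i{i}" for i in range(n)], seed)


class TestSplitArithmetic:
    @pytest.mark.parametrize("reduction,expected", [
        (0.0, (3523, 1006, 505)),
        (0.5, (1761, 503, 505)),
        (0.2, (2818, 804, 505)),
        (0.7, (1056, 301, 505)),
    ])
    def test_paper_scale_counts(self, reduction, expected):
        """n=5034 with 70/20/10 fractions and train+val-only reduction."""
        assert split_sizes(5034, SplitPlan(reduction=reduction)) == expected

    def test_partition_contract_at_zero_reduction(self):
        ds = _balanced_set(100)
        tr, va, te = split_dataset(ds, SplitPlan(seed=3))
        ids = [*tr.ids, *va.ids, *te.ids]
        assert len(set(ids)) == 100  # disjoint
        assert sorted(ids) == sorted(ds.ids)  # union covers

    def test_test_partition_unchanged_by_reduction(self):
        ds = _balanced_set(100)
        _, _, te0 = split_dataset(ds, SplitPlan(reduction=0.0, seed=1))
        _, _, te5 = split_dataset(ds, SplitPlan(reduction=0.5, seed=1))
        assert te0.ids == te5.ids

    def test_stratification_within_one(self):
        ds = _balanced_set(104, seed=5)
        for red in (0.0, 0.5):
            for part in split_dataset(ds, SplitPlan(reduction=red, seed=2)):
                ones = int(part.labels.sum())
                assert abs(ones - (len(part) - ones)) <= 1

    def test_disallowed_reduction_rejected(self):
        with pytest.raises(ValueError):
            SplitPlan(reduction=0.3)

    def test_seed_stability(self):
        ds = _balanced_set(60)
        a = split_dataset(ds, SplitPlan(seed=9))
        b = split_dataset(ds, SplitPlan(seed=9))
        assert all(x.ids == y.ids for x, y in zip(a, b))


class TestAccuracy:
    def test_threshold_at_half_inclusive(self):
        assert accuracy([1, 0], [0.5, 0.49]) == 1.0


class TestTrainingLoops:
    @pytest.fixture(scope="class")
    def small_pretext(self):
        cfg = PhantomConfig(image_size=32, n_per_class=30,
                            noise=NoiseConfig.off(), seed=7)
        images = generate_dataset(cfg).images
        return make_noise_pretext(images, noise_factor=0.2, seed=0)

    def test_zero_epochs_is_identity(self, small_pretext):
        model = build_model(encoder_spec((32, 32, 3)), seed=0)
        before = model.checksum()
        model, log = train_pretext(small_pretext, model,
                                   TrainConfig(epochs=0, seed=0))
        assert model.checksum() == before
        assert len(log) == 0

    def test_incompatible_loss_rejected(self, small_pretext):
        model = build_model(encoder_spec((32, 32, 3)), seed=0)
        with pytest.raises(ValueError, match="incompatible"):
            train_pretext(small_pretext, model,
                          TrainConfig(loss=LossSpec("mse")))

    def test_separable_pretext_learned_quickly(self, small_pretext):
        """noise_factor=0.2 is plainly visible: the pretext classifier
        passes 95 percent validation accuracy within 5 epochs
        (median of 3 seeds)."""
        accs = []
        for seed in range(3):
            model = build_model(encoder_spec((32, 32, 3)), seed=seed)
            cfg = TrainConfig(epochs=5, learning_rate=1e-3, seed=seed)
            _, log = train_pretext(small_pretext, model, cfg)
            accs.append(log.to_frame()["val_acc"].iloc[-1])
        assert np.median(accs) > 0.95

    def test_loss_decreases(self, small_pretext):
        model = build_model(encoder_spec((32, 32, 3)), seed=1)
        _, log = train_pretext(small_pretext, model,
                               TrainConfig(epochs=3, learning_rate=1e-3,
                                           seed=1))
        frame = log.to_frame()
        assert frame["train_loss"].iloc[-1] < frame["train_loss"].iloc[0]

    def test_same_seed_identical_log(self, small_pretext):
        logs = []
        for _ in range(2):
            model = build_model(encoder_spec((32, 32, 3)), seed=2)
            _, log = train_pretext(small_pretext, model,
                                   TrainConfig(epochs=2, seed=2))
            logs.append(log.to_frame())
        pd.testing.assert_frame_equal(logs[0], logs[1])

    def test_grouped_holdout_keeps_siblings_together(self, small_pretext):
        """An original and its transformed copy always land in one fold."""
        from cardiossl.training import _grouped_holdout
        rng = np.random.default_rng(0)
        tr, va = _grouped_holdout(small_pretext, 0.2, rng)
        src = small_pretext.provenance["source_id"].to_numpy()
        assert set(src[tr]) & set(src[va]) == set()

    def test_default_noise_level_pretext_learnable(self):
        """The desk-scale noise pretext (sigma 0.05 on 32 px phantoms)
        passes 95 percent validation accuracy within 5 epochs
        (3-seed median)."""
        cfg = PhantomConfig(image_size=32, n_per_class=50,
                            noise=NoiseConfig.off(), seed=0)
        images = generate_dataset(cfg).images
        accs = []
        for seed in range(3):
            model = build_model(encoder_spec((32, 32, 3)), seed=seed)
            ds = make_noise_pretext(images, noise_factor=0.05, seed=seed)
            _, log = train_pretext(ds, model,
                                   TrainConfig(epochs=5, learning_rate=1e-3,
                                               seed=seed))
            accs.append(log.to_frame()["val_acc"].iloc[-1])
        assert np.median(accs) > 0.95

    def test_autoencoder_training_improves_reconstruction(self):
        """Training reduces reconstruction MSE versus the untrained
        autoencoder (3-seed median)."""
        from cardiossl.models import autoencoder_spec
        from cardiossl.pretext import (LossSpec, make_reconstruction_pretext,
                                       mse_loss)
        cfg = PhantomConfig(image_size=32, n_per_class=50,
                            noise=NoiseConfig.off(), seed=0)
        images = generate_dataset(cfg).images
        deltas = []
        for seed in range(3):
            model = build_model(autoencoder_spec((32, 32, 3)), seed=seed)
            ds = make_reconstruction_pretext(images)
            before = mse_loss(images, model.predict(images))
            model, _ = train_pretext(
                ds, model, TrainConfig(epochs=10, learning_rate=1e-3,
                                       loss=LossSpec("mse"), seed=seed))
            deltas.append(before - mse_loss(images, model.predict(images)))
        assert np.median(deltas) > 0

    def test_contrastive_loop_decreases_nt_xent(self):
        from cardiossl.models import simclr_model
        from cardiossl.pretext import LossSpec, make_simclr_views
        cfg = PhantomConfig(image_size=32, n_per_class=40,
                            noise=NoiseConfig.off(), seed=1)
        images = generate_dataset(cfg).images
        model = simclr_model(encoder_spec((32, 32, 3)), seed=0)
        ds = make_simclr_views(images, seed=0)
        _, log = train_pretext(ds, model,
                               TrainConfig(epochs=2, learning_rate=1e-3,
                                           loss=LossSpec("nt_xent"), seed=0))
        frame = log.to_frame()
        assert frame["train_loss"].iloc[-1] < frame["train_loss"].iloc[0]
        assert np.isfinite(frame["train_loss"]).all()

    def test_downstream_zero_epochs_identity(self):
        ds = _balanced_set(40, seed=1)
        model = transfer_surgery(build_model(encoder_spec((16, 16, 3)),
                                             seed=0), seed=0)
        before = model.checksum()
        model, log = train_downstream(model, ds, ds,
                                      TrainConfig(epochs=0, seed=0))
        assert model.checksum() == before
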