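"""Splits, augmentation pairing, composite loss, LR schedule, training loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raman3d.errors import ConfigError, SplitError
from raman3d.nn.model import NetworkSpec, build_network
from raman3d.training import (
    AugmentFlags,
    AugmentRecord,
    TrainConfig,
    apply_augment,
    augment_pair,
    composite_loss,
    load_checkpoint,
    lr_at_epoch,
    mix_pairs,
    save_checkpoint,
    split_dataset,
    train,
)


class TestSplit:
    def test_published_sizes_at_144(self):
        """144 items at 0.8/0.1/0.1 partition into 115/14/15."""
        split = split_dataset(144, (0.8, 0.1, 0.1), seed=0)
        assert split.sizes == (115, 14, 15)

    def test_exact_fractions_small_n(self):
        assert split_dataset(10, (0.8, 0.1, 0.1), seed=1).sizes == (8, 1, 1)

    @settings(max_examples=100, deadline=None)
    @given(n=st.integers(3, 500), seed=st.integers(0, 2**31 - 1))
    def test_disjoint_and_exhaustive(self, n, seed):
        split = split_dataset(n, seed=seed)
        combined = set(split.train_idx) | set(split.val_idx) | set(split.test_idx)
        assert combined == set(range(n))
        assert len(split.train_idx) + len(split.val_idx) + len(split.test_idx) == n

    def test_seed_shuffles_indices(self):
        a = split_dataset(50, seed=1)
        b = split_dataset(50, seed=2)
        assert a.train_idx != b.train_idx

    def test_too_few_items_rejected(self):
        with pytest.raises(SplitError):
            split_dataset(2)

    def test_bad_fractions_rejected(self):
        with pytest.raises(SplitError):
            split_dataset(10, (0.5, 0.2, 0.2))


class TestAugmentation:
    def test_flip_is_involution(self, rng):
        cube = rng.uniform(size=(6, 6, 5))
        record = AugmentRecord(flip_h=True)
        np.testing.assert_array_equal(apply_augment(record, apply_augment(record, cube)), cube)

    def test_four_quarter_turns_identity(self, rng):
        cube = rng.uniform(size=(6, 6, 5))
        out = cube
        for _ in range(4):
            out = apply_augment(AugmentRecord(n_rot90=1), out)
        np.testing.assert_array_equal(out, cube)

    def test_pairing_preserved_bit_exactly(self, rng):
        """Replaying the recorded transform on the clean member reproduces
        the augmented clean member."""
        noisy, clean = rng.uniform(size=(8, 8, 6)), rng.uniform(size=(8, 8, 6))
        for seed in range(10):
            noisy2, clean2, record = augment_pair(noisy, clean, AugmentFlags(), seed=seed)
            np.testing.assert_array_equal(apply_augment(record, clean), clean2)
            np.testing.assert_array_equal(apply_augment(record, noisy), noisy2)

    def test_spectral_axis_never_permuted(self, rng):
        noisy = rng.uniform(size=(4, 4, 7))
        for seed in range(10):
            noisy2, _, _ = augment_pair(noisy, noisy, AugmentFlags(), seed=seed)
            # band means are invariant under purely spatial transforms
            np.testing.assert_allclose(noisy2.mean(axis=(0, 1)), noisy.mean(axis=(0, 1)))

    def test_mix_endpoints(self, rng):
        pair_a = (rng.uniform(size=(4, 4, 3)), rng.uniform(size=(4, 4, 3)))
        pair_b = (rng.uniform(size=(4, 4, 3)), rng.uniform(size=(4, 4, 3)))
        na, ca = mix_pairs(pair_a, pair_b, lam=1.0)
        np.testing.assert_array_equal(na, pair_a[0])
        np.testing.assert_array_equal(ca, pair_a[1])
        nb, cb = mix_pairs(pair_a, pair_b, lam=0.0)
        np.testing.assert_array_equal(nb, pair_b[0])
        np.testing.assert_array_equal(cb, pair_b[1])


class TestCompositeLoss:
    def test_zero_iff_equal(self, rng):
        a = rng.uniform(size=(3, 3, 3))
        assert composite_loss(a, a) == 0.0
        assert composite_loss(a, a + 0.1) > 0.0

    def test_unit_residual_closed_form(self):
        """Residual ≡ 1 with weights (0.1, 0.9): 0.1·1 + 0.9·1 = 1.0."""
        a = np.zeros((4, 4))
        b = np.ones((4, 4))
        assert composite_loss(a, b, 0.1, 0.9) == pytest.approx(1.0)

    def test_matches_elementwise_oracle(self, rng):
        a, b = rng.normal(size=24), rng.normal(size=24)
        l1 = sum(abs(x - y) for x, y in zip(a, b)) / 24
        l2 = sum((x - y) ** 2 for x, y in zip(a, b)) / 24
        assert abs(composite_loss(a, b, 0.1, 0.9) - (0.1 * l1 + 0.9 * l2)) <= 1e-7

    def test_permutation_invariance_and_mse_scaling(self, rng):
        a, b = rng.normal(size=30), rng.normal(size=30)
        perm = rng.permutation(30)
        assert composite_loss(a, b) == pytest.approx(composite_loss(a[perm], b[perm]))
        # pure-MSE part scales quadratically under residual scaling
        for factor in (2.0, 3.0):
            scaled = composite_loss(a + factor * (b - a), a, 0.0, 1.0)
            assert scaled == pytest.approx(factor**2 * composite_loss(b, a, 0.0, 1.0))

    def test_negative_weights_rejected(self):
        with pytest.raises(ConfigError):
            composite_loss(np.zeros(3), np.ones(3), -0.1, 1.1)


class TestSchedule:
    @pytest.mark.parametrize("epoch,expected", [(1, 0.001), (59, 0.001), (60, 0.0001), (100, 0.0001)])
    def test_step_schedule(self, epoch, expected):
        assert lr_at_epoch(epoch, TrainConfig()) == expected

    def test_epoch_out_of_range(self):
        with pytest.raises(ConfigError):
            lr_at_epoch(0, TrainConfig())
        with pytest.raises(ConfigError):
            lr_at_epoch(101, TrainConfig())

    def test_default_weights_sum_to_one(self):
        config = TrainConfig()
        assert abs(config.w_l1 + config.w_mse - 1.0) < 1e-12


def _toy_pairs(rng, n, shape=(8, 8, 16)):
    pairs = []
    for _ in range(n):
        clean = np.clip(rng.normal(0.4, 0.15, size=shape), 0, 1)
        noisy = np.clip(clean + rng.normal(0, 0.1, size=shape), 0, 1)
        pairs.append((noisy, clean))
    return pairs


def _toy_config(**kw):
    base = dict(epochs=3, batch_size=2, lr_drop_epoch=2, patch=(8, 8, 16), seed=0)
    base.update(kw)
    return TrainConfig(**base)


class TestTrainLoop:
    def test_deterministic_histories(self, rng):
        pairs = _toy_pairs(rng, 4)
        histories = []
        for _ in range(2):
            model = build_network(NetworkSpec(n_levels=1, base_channels=8, seed=1, use_fusion=False))
            _, history = train(model, pairs[:3], pairs[3:], _toy_config())
            histories.append(history)
        assert histories[0] == histories[1]
        assert len(histories[0]) == 3

    def test_checkpoint_roundtrip_identical_predictions(self, rng, tmp_path):
        pairs = _toy_pairs(rng, 3)
        model = build_network(NetworkSpec(n_levels=1, base_channels=8, seed=2, use_fusion=False))
        model, _ = train(model, pairs[:2], pairs[2:], _toy_config(epochs=2))
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path, meta={"note": "test"})
        restored, header = load_checkpoint(path)
        assert header["meta"]["note"] == "test"
        from raman3d.nn.model import denoise_cube_array

        x = pairs[0][0]
        np.testing.assert_array_equal(
            denoise_cube_array(model, x), denoise_cube_array(restored, x)
        )

    def test_training_reduces_validation_loss(self, rng):
        """Descent on the run's own history, required for ≥4 of 5 seeds."""
        wins = 0
        for seed in range(5):
            gen = np.random.default_rng(seed)
            pairs = _toy_pairs(gen, 5)
            model = build_network(NetworkSpec(n_levels=1, base_channels=8, seed=seed, use_fusion=False))
            _, history = train(
                model, pairs[:4], pairs[4:], _toy_config(epochs=8, lr_drop_epoch=6, seed=seed)
            )
            if history[-1]["val_loss"] < history[0]["val_loss"]:
                wins += 1
        assert wins >= 4

    def test_empty_training_set_rejected(self, rng):
        model = build_network(NetworkSpec(n_levels=1, base_channels=8, use_fusion=False))
        with pytest.raises(ConfigError):
            train(model, [], _toy_pairs(rng, 1), _toy_config())
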