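"""Dataset splitting, paired augmentation, composite loss, and training.

The training recipe follows the published protocol for this denoiser: Adam,
batch size 2, 100 epochs with the learning rate dropping from 1e-3 to 1e-4
at epoch 60, and a composite objective ``0.1·L1 + 0.9·MSE`` on normalized
cubes.  Desk-scale runs shrink epochs/network, not the recipe's structure.

Splits use the floor/floor/remainder rule — the only rounding consistent
with 144 items at fractions 0.8/0.1/0.1 giving (115, 14, 15).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from raman3d.errors import ConfigError, ShapeError, SplitError
from raman3d.nn import functional as F
from raman3d.nn.autograd import Tensor, no_grad
from raman3d.nn.model import MultiResUNet3D, NetworkSpec, build_network
from raman3d.nn.optim import Adam

CHECKPOINT_FORMAT_VERSION = "1.0"


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DatasetSplit:
    train_idx: tuple[int, ...]
    val_idx: tuple[int, ...]
    test_idx: tuple[int, ...]
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.train_idx), len(self.val_idx), len(self.test_idx)


def split_dataset(
    n: int,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> DatasetSplit:
    """Shuffle ``n`` indices by ``seed`` and partition train/val/test.

    Sizes are ``floor(n·f_train)``, ``floor(n·f_val)`` and the remainder for
    test, so every index lands in exactly one subset.
    """
    if any(f <= 0 for f in fractions):
        raise SplitError(f"fractions must be positive, got {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise SplitError(f"fractions must sum to 1, got {fractions}")
    if n < 3:
        raise SplitError(f"cannot split {n} items into three non-empty-capable subsets")
    n_train = math.floor(n * fractions[0])
    n_val = math.floor(n * fractions[1])
    order = np.random.default_rng(seed).permutation(n)
    return DatasetSplit(
        train_idx=tuple(int(i) for i in order[:n_train]),
        val_idx=tuple(int(i) for i in order[n_train : n_train + n_val]),
        test_idx=tuple(int(i) for i in order[n_train + n_val :]),
        fractions=fractions,
    )


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AugmentFlags:
    """Which augmentations the training loop may draw."""

    flip: bool = True
    rotate: bool = True
    mix: bool = False  # pairwise convex blending; experimental, off by default


@dataclass(frozen=True)
class AugmentRecord:
    """The exact spatial transform applied to a pair (replayable)."""

    flip_h: bool = False
    flip_w: bool = False
    n_rot90: int = 0  # quarter turns in the H×W plane


def apply_augment(record: AugmentRecord, cube: np.ndarray) -> np.ndarray:
    """Replay a recorded transform on one H×W×B array."""
    out = cube
    if record.flip_h:
        out = out[::-1, :, :]
    if record.flip_w:
        out = out[:, ::-1, :]
    if record.n_rot90 % 4:
        out = np.rot90(out, k=record.n_rot90 % 4, axes=(0, 1))
    return np.ascontiguousarray(out)


def augment_pair(
    noisy: np.ndarray,
    clean: np.ndarray,
    flags: AugmentFlags = AugmentFlags(),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, AugmentRecord]:
    """Draw one random spatial transform and apply it to BOTH pair members.

    Flips reverse a spatial axis; rotations are 90° multiples in the H×W
    plane (drawn only when the spatial extent is square, otherwise limited
    to half turns); the spectral axis is never permuted.  Returns the
    transformed pair plus the replayable :class:`AugmentRecord`.
    """
    if noisy.shape != clean.shape:
        raise ShapeError(f"pair members differ in shape: {noisy.shape} vs {clean.shape}")
    rng = np.random.default_rng(seed)
    flip_h = bool(flags.flip and rng.integers(2))
    flip_w = bool(flags.flip and rng.integers(2))
    n_rot = 0
    if flags.rotate:
        choices = (0, 1, 2, 3) if noisy.shape[0] == noisy.shape[1] else (0, 2)
        n_rot = int(rng.choice(choices))
    record = AugmentRecord(flip_h=flip_h, flip_w=flip_w, n_rot90=n_rot)
    return apply_augment(record, noisy), apply_augment(record, clean), record


def mix_pairs(
    pair_a: tuple[np.ndarray, np.ndarray],
    pair_b: tuple[np.ndarray, np.ndarray],
    lam: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Convex blend of two pairs with weight ``lam`` on pair A.

    The same λ is applied to inputs and targets so the noisy↔clean pairing
    is preserved; ``lam=1`` returns pair A exactly, ``lam=0`` pair B.
    """
    if not 0.0 <= lam <= 1.0:
        raise ConfigError(f"mixing weight must be in [0, 1], got {lam}")
    noisy = lam * pair_a[0] + (1.0 - lam) * pair_b[0]
    clean = lam * pair_a[1] + (1.0 - lam) * pair_b[1]
    if lam == 1.0:
        return pair_a[0].copy(), pair_a[1].copy()
    if lam == 0.0:
        return pair_b[0].copy(), pair_b[1].copy()
    return noisy, clean


# ---------------------------------------------------------------------------
# loss and schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters; defaults mirror the published recipe."""

    epochs: int = 100
    batch_size: int = 2
    lr_initial: float = 0.001
    lr_drop_epoch: int = 60
    lr_after_drop: float = 0.0001
    w_l1: float = 0.1
    w_mse: float = 0.9
    patch: tuple[int, int, int] = (32, 32, 64)
    crops_per_cube: int = 2
    seed: int = 0
    augment: AugmentFlags = field(default_factory=AugmentFlags)
    mix_beta: float = 0.4  # Beta(a, a) for the mixing draw when enabled
    deterministic: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if not 1 <= self.lr_drop_epoch <= self.epochs:
            raise ConfigError("lr_drop_epoch must lie within [1, epochs]")
        if self.w_l1 < 0 or self.w_mse < 0:
            raise ConfigError("loss weights must be nonnegative")


def composite_loss(pred, target, w_l1: float = 0.1, w_mse: float = 0.9):
    """Weighted L1 + MSE objective: ``w_l1·mean|d| + w_mse·mean d²``.

    Works on plain arrays (returns a float) or autograd tensors (returns a
    scalar Tensor for backprop).
    """
    if w_l1 < 0 or w_mse < 0:
        raise ConfigError(f"loss weights must be nonnegative, got {(w_l1, w_mse)}")
    if isinstance(pred, Tensor) or isinstance(target, Tensor):
        diff = F.sub(pred, target)
        return F.add(F.scale(F.mean_all(F.absolute(diff)), w_l1), F.scale(F.mean_all(F.square(diff)), w_mse))
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ShapeError(f"loss operands differ in shape: {pred.shape} vs {target.shape}")
    diff = pred - target
    return float(w_l1 * np.abs(diff).mean() + w_mse * (diff * diff).mean())


def lr_at_epoch(epoch: int, config: TrainConfig) -> float:
    """Step schedule: initial LR before the drop epoch, reduced LR from it on."""
    if not 1 <= epoch <= config.epochs:
        raise ConfigError(f"epoch {epoch} outside [1, {config.epochs}]")
    return config.lr_initial if epoch < config.lr_drop_epoch else config.lr_after_drop


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def _random_crop(rng: np.random.Generator, pair: tuple[np.ndarray, np.ndarray], patch: tuple[int, int, int]):
    noisy, clean = pair
    h, w, b = noisy.shape
    ph, pw, pb = (min(p, e) for p, e in zip(patch, (h, w, b)))
    i = int(rng.integers(0, h - ph + 1))
    j = int(rng.integers(0, w - pw + 1))
    l = int(rng.integers(0, b - pb + 1))
    return noisy[i : i + ph, j : j + pw, l : l + pb], clean[i : i + ph, j : j + pw, l : l + pb]


def evaluate_loss(model: MultiResUNet3D, pairs: Sequence[tuple[np.ndarray, np.ndarray]], config: TrainConfig) -> float:
    """Mean composite loss of the model over a list of (noisy, clean) pairs."""
    model.eval()
    total = 0.0
    with no_grad():
        for noisy, clean in pairs:
            x = Tensor(noisy.astype(np.float32)[None, None])
            pred = model(x).data[0, 0]
            total += composite_loss(pred, clean, config.w_l1, config.w_mse)
    model.train()
    return total / max(len(pairs), 1)


def train(
    model: MultiResUNet3D,
    train_pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    val_pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    config: TrainConfig,
) -> tuple[MultiResUNet3D, list[dict]]:
    """Run the seeded Adam training loop.

    ``train_pairs``/``val_pairs`` are lists of (noisy, clean) H×W×B arrays,
    already min-max normalized.  Runs exactly ``config.epochs`` epochs with
    the stepped LR schedule, random crops and paired augmentation; retains
    the best-on-validation parameter state and loads it back into the model
    at the end.  Returns the model and a per-epoch history
    ``[{epoch, lr, train_loss, val_loss}, ...]``.
    """
    if len(train_pairs) == 0:
        raise ConfigError("training set is empty")
    for noisy, clean in list(train_pairs) + list(val_pairs):
        if noisy.shape != clean.shape:
            raise ShapeError("train/val pairs must be congruent")
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), lr=config.lr_initial)
    steps_per_epoch = max(1, math.ceil(len(train_pairs) * config.crops_per_cube / config.batch_size))

    history: list[dict] = []
    best_val = np.inf
    best_state: Optional[dict] = None

    for epoch in range(1, config.epochs + 1):
        optimizer.lr = lr_at_epoch(epoch, config)
        model.train()
        epoch_loss = 0.0
        for step in range(steps_per_epoch):
            batch_noisy, batch_clean = [], []
            for _ in range(config.batch_size):
                k = int(rng.integers(0, len(train_pairs)))
                noisy, clean = _random_crop(rng, train_pairs[k], config.patch)
                noisy, clean, _rec = augment_pair(noisy, clean, config.augment, seed=int(rng.integers(2**31)))
                if config.augment.mix and len(train_pairs) > 1:
                    lam = float(rng.beta(config.mix_beta, config.mix_beta))
                    k2 = int(rng.integers(0, len(train_pairs)))
                    other = _random_crop(rng, train_pairs[k2], config.patch)
                    noisy, clean = mix_pairs((noisy, clean), other, lam)
                batch_noisy.append(noisy)
                batch_clean.append(clean)
            x = Tensor(np.stack(batch_noisy)[:, None].astype(np.float32))
            y = np.stack(batch_clean)[:, None].astype(np.float32)
            pred = model(x)
            loss = composite_loss(pred, Tensor(y), config.w_l1, config.w_mse)
            loss_val = loss.item()
            if not np.isfinite(loss_val):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {step + 1}: {loss_val}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += loss_val
        val_loss = evaluate_loss(model, val_pairs, config) if len(val_pairs) else np.nan
        history.append(
            dict(
                epoch=epoch,
                lr=optimizer.lr,
                train_loss=epoch_loss / steps_per_epoch,
                val_loss=val_loss,
            )
        )
        if len(val_pairs) and val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()

    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: MultiResUNet3D, path: str | os.PathLike, meta: Optional[dict] = None) -> None:
    """Serialize weights + NetworkSpec (+optional metadata) to one .npz file."""
    payload = {f"param::{k}": v for k, v in model.state_dict().items()}
    header = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "network_spec": model.spec.to_dict(),
        "meta": meta or {},
    }
    payload["header_json"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    np.savez(os.fspath(path), **payload)


def load_checkpoint(path: str | os.PathLike) -> tuple[MultiResUNet3D, dict]:
    """Rebuild a model from a checkpoint; returns (model, header metadata)."""
    with np.load(os.fspath(path)) as archive:
        header = json.loads(bytes(archive["header_json"]).decode())
        state = {
            key[len("param::") :]: archive[key] for key in archive.files if key.startswith("param::")
        }
    model = build_network(NetworkSpec.from_dict(header["network_spec"]))
    model.load_state_dict(state)
    model.eval()
    return model, header
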