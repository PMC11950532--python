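"""Brain-age models: 3-D convolutional autoencoder, encoder transfer,
regression head, and windowed checkpoint selection.

The training scheme is two-stage transfer learning.  A convolutional
autoencoder (CAE) is first trained to reconstruct volumes (MSE loss).
Its encoder weights are then copied into an age-regression network and
*frozen*; only the freshly initialized dense head is updated while the
regressor trains on (volume, age) pairs with MSE loss.  For each trained
model, the checkpoint with the best validation score within the last
``selection_window`` epochs is kept (reconstruction MSE for the CAE,
age MAE for the regressor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn

__all__ = [
    "NetSpec",
    "TrainConfig",
    "Checkpoint",
    "CheckpointStore",
    "build_cae",
    "build_regressor",
    "transfer_encoder",
    "train_cae",
    "train_regressor",
    "select_best_checkpoint",
    "predict_age",
]


@dataclass(frozen=True)
class NetSpec:
    """Architecture: B stride-2 conv blocks (3x3x3, ReLU), a dense latent,
    and a dense regression head ending in a single scalar (years)."""

    input_shape: tuple[int, int, int] = (32, 32, 32)
    in_channels: int = 1
    encoder_widths: tuple[int, ...] = (8, 16, 32)
    latent_dim: int = 64
    head_widths: tuple[int, ...] = (32,)

    def __post_init__(self):
        if not self.encoder_widths:
            raise ValueError("encoder_widths must be nonempty")
        if any(w < 1 for w in self.encoder_widths) or self.latent_dim < 1:
            raise ValueError("all widths must be >= 1")
        factor = 2 ** len(self.encoder_widths)
        if any(n % factor for n in self.input_shape):
            raise ValueError(
                f"input_shape {self.input_shape} must be divisible by "
                f"2^{len(self.encoder_widths)} for the mirrored decoder")

    @property
    def bottleneck_shape(self) -> tuple[int, ...]:
        factor = 2 ** len(self.encoder_widths)
        spatial = tuple(n // factor for n in self.input_shape)
        return (self.encoder_widths[-1],) + spatial

    @property
    def bottleneck_size(self) -> int:
        return int(np.prod(self.bottleneck_shape))


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    batch_size: int = 16
    learning_rate: float = 1e-3
    loss: str = "mse"
    selection_window: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.selection_window > self.epochs:
            raise ValueError("selection_window must be <= epochs")
        if self.loss != "mse":
            raise ValueError("only MSE loss is supported")


@dataclass
class Checkpoint:
    epoch: int                      # 1-based
    score: float                    # validation MSE (CAE) or MAE (regressor)
    state: list[np.ndarray] | None  # kept only inside the retention window


class CheckpointStore:
    """Per-epoch validation scores with a ring buffer of parameter snapshots.

    Scores are kept for every epoch; parameter snapshots only for the most
    recent ``retain`` epochs, which bounds memory while still covering the
    selection window.
    """

    def __init__(self, retain: int):
        if retain < 1:
            raise ValueError("retain must be >= 1")
        self.retain = retain
        self.checkpoints: list[Checkpoint] = []

    def add(self, epoch: int, score: float, state: list[np.ndarray]):
        if self.checkpoints and epoch <= self.checkpoints[-1].epoch:
            raise ValueError("epoch indices must be strictly increasing")
        self.checkpoints.append(Checkpoint(epoch, float(score),
                                           [a.copy() for a in state]))
        for ck in self.checkpoints[:-self.retain]:
            ck.state = None

    @property
    def scores(self) -> list[float]:
        return [ck.score for ck in self.checkpoints]

    def __len__(self):
        return len(self.checkpoints)


def select_best_checkpoint(store: CheckpointStore, window: int,
                           criterion: str = "min_val_score"
                           ) -> tuple[list[np.ndarray], int]:
    """Best (lowest) validation score among the last ``window`` epochs.

    Ties go to the earliest epoch in the window.  Returns the parameter
    snapshot and the chosen (1-based) epoch.
    """
    if criterion != "min_val_score":
        raise ValueError(f"unknown criterion {criterion!r}")
    if len(store) == 0:
        raise ValueError("checkpoint store is empty")
    candidates = store.checkpoints[-window:]
    best = min(candidates, key=lambda ck: (ck.score, ck.epoch))
    if best.state is None:
        raise ValueError(
            f"snapshot for epoch {best.epoch} was evicted; increase the "
            f"store's retention to cover the selection window")
    return [a.copy() for a in best.state], best.epoch


# ---------------------------------------------------------------------------
# model construction


def _encoder_layers(spec: NetSpec, rng) -> list[nn.Layer]:
    layers: list[nn.Layer] = []
    prev = spec.in_channels
    for w in spec.encoder_widths:
        layers.append(nn.Conv3d(prev, w, rng))
        layers.append(nn.ReLU())
        prev = w
    layers.append(nn.Flatten())
    layers.append(nn.Dense(spec.bottleneck_size, spec.latent_dim, rng))
    return layers


def build_cae(spec: NetSpec, seed: int = 0) -> nn.Sequential:
    """Autoencoder: encoder to a dense latent, mirrored decoder back."""
    rng = np.random.default_rng([int(seed), 0xCAE])
    layers = _encoder_layers(spec, rng)
    layers.append(nn.Dense(spec.latent_dim, spec.bottleneck_size, rng))
    layers.append(nn.ReLU())
    layers.append(nn.Reshape(spec.bottleneck_shape))
    widths = list(spec.encoder_widths)
    prev = widths[-1]
    for w in reversed(widths[:-1]):
        layers.append(nn.ConvTranspose3d(prev, w, rng))
        layers.append(nn.ReLU())
        prev = w
    layers.append(nn.ConvTranspose3d(prev, spec.in_channels, rng))
    return nn.Sequential(layers)


def n_encoder_params(spec: NetSpec) -> int:
    """Number of Parameter objects making up the encoder."""
    return 2 * len(spec.encoder_widths) + 2  # (W, b) per conv + latent Dense


def build_regressor(spec: NetSpec, seed: int = 0) -> nn.Sequential:
    """Encoder + dense regression head producing one scalar age (years)."""
    rng = np.random.default_rng([int(seed), 0x4EAD])
    layers = _encoder_layers(spec, rng)
    prev = spec.latent_dim
    for w in spec.head_widths:
        layers.append(nn.Dense(prev, w, rng))
        layers.append(nn.ReLU())
        prev = w
    layers.append(nn.Dense(prev, 1, rng))
    return nn.Sequential(layers)


def transfer_encoder(cae_state: list[np.ndarray], spec: NetSpec,
                     seed: int = 0) -> nn.Sequential:
    """Copy a trained CAE's encoder into a fresh regressor and freeze it.

    ``cae_state`` is the CAE's full parameter snapshot (encoder first).
    The head keeps its seed-fresh initialization; only the head trains.
    """
    model = build_regressor(spec, seed=seed)
    n_enc = n_encoder_params(spec)
    enc_params = model.params()[:n_enc]
    if len(cae_state) < n_enc:
        raise ValueError(f"CAE snapshot has {len(cae_state)} arrays, "
                         f"encoder needs {n_enc}")
    for i, (p, v) in enumerate(zip(enc_params, cae_state[:n_enc])):
        v = np.asarray(v, dtype=np.float64)
        if p.value.shape != v.shape:
            raise ValueError(
                f"encoder layout mismatch at parameter {i}: "
                f"regressor {p.value.shape} vs CAE snapshot {v.shape}")
        p.value = v.copy()
        p.grad = np.zeros_like(p.value)
        p.trainable = False
    return model


def encoder_state(model: nn.Sequential, spec: NetSpec) -> list[np.ndarray]:
    """Copies of the encoder parameter arrays of a CAE or regressor."""
    return [p.value.copy() for p in model.params()[:n_encoder_params(spec)]]


# ---------------------------------------------------------------------------
# training


def _check_volumes(volumes: np.ndarray, spec: NetSpec, name: str) -> np.ndarray:
    volumes = np.asarray(volumes, dtype=np.float64)
    want = (spec.in_channels,) + tuple(spec.input_shape)
    if volumes.ndim != 5 or volumes.shape[1:] != want:
        raise ValueError(f"{name}: expected shape (n,)+{want}, got {volumes.shape}")
    return volumes


def _epoch_batches(n: int, batch_size: int, rng) -> list[np.ndarray]:
    order = rng.permutation(n)
    return [order[i:i + batch_size] for i in range(0, n, batch_size)]


def _train_loop(model: nn.Sequential, target_fn, val_fn,
                x_train: np.ndarray, cfg: TrainConfig) -> tuple[CheckpointStore, pd.DataFrame]:
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    store = CheckpointStore(retain=cfg.selection_window)
    rng = np.random.default_rng([int(cfg.seed), 0x10A])
    rows = []
    for epoch in range(1, cfg.epochs + 1):
        losses = []
        for idx in _epoch_batches(len(x_train), cfg.batch_size, rng):
            xb = x_train[idx]
            pred = model.forward(xb)
            loss, grad = nn.mse_loss(pred, target_fn(idx, xb))
            model.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss)
        val_score = val_fn(model)
        store.add(epoch, val_score, model.state_dict())
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "val_score": val_score})
    return store, pd.DataFrame(rows)


def _batched_forward(model: nn.Sequential, x: np.ndarray,
                     batch_size: int = 32) -> np.ndarray:
    outs = [model.forward(x[i:i + batch_size]) for i in range(0, len(x), batch_size)]
    return np.concatenate(outs, axis=0)


def train_cae(train_volumes: np.ndarray, val_volumes: np.ndarray,
              spec: NetSpec, cfg: TrainConfig) -> tuple[CheckpointStore, pd.DataFrame]:
    """Train the autoencoder; validation score is reconstruction MSE."""
    x_train = _check_volumes(train_volumes, spec, "train_volumes")
    x_val = _check_volumes(val_volumes, spec, "val_volumes")
    if len(x_val) == 0:
        raise ValueError("validation set must be nonempty")
    if len(x_train) == 0:
        raise ValueError("training set must be nonempty")
    model = build_cae(spec, seed=cfg.seed)

    def val_fn(m):
        recon = _batched_forward(m, x_val)
        return float(np.mean((recon - x_val) ** 2))

    return _train_loop(model, lambda idx, xb: xb, val_fn, x_train, cfg)


def train_regressor(model: nn.Sequential,
                    train_volumes: np.ndarray, train_ages: np.ndarray,
                    val_volumes: np.ndarray, val_ages: np.ndarray,
                    spec: NetSpec, cfg: TrainConfig
                    ) -> tuple[CheckpointStore, pd.DataFrame]:
    """Train the age head (encoder frozen); validation score is age MAE."""
    x_train = _check_volumes(train_volumes, spec, "train_volumes")
    x_val = _check_volumes(val_volumes, spec, "val_volumes")
    y_train = np.asarray(train_ages, dtype=np.float64).reshape(-1, 1)
    y_val = np.asarray(val_ages, dtype=np.float64).reshape(-1, 1)
    if len(x_train) == 0:
        raise ValueError("training set must be nonempty")
    if len(y_train) != len(x_train) or len(y_val) != len(x_val):
        raise ValueError("ages must align with volumes")
    if not (np.all(np.isfinite(y_train)) and np.all(np.isfinite(y_val))):
        raise ValueError("ages must be finite")
    if all(p.trainable for p in model.params()):
        raise ValueError("regressor must have a frozen (transferred) encoder")

    # start the output at the training-set mean age so epochs are spent on
    # the age signal, not on shifting the output scale
    out_bias = model.params()[-1]
    if out_bias.trainable and np.all(out_bias.value == 0.0):
        out_bias.value[...] = float(y_train.mean())

    def val_fn(m):
        pred = _batched_forward(m, x_val)
        return float(np.mean(np.abs(pred - y_val)))

    return _train_loop(model, lambda idx, xb: y_train[idx], val_fn, x_train, cfg)


def predict_age(model: nn.Sequential, volumes: np.ndarray,
                batch_size: int = 32) -> np.ndarray:
    """Predicted age in years, one finite scalar per input volume."""
    volumes = np.asarray(volumes, dtype=np.float64)
    if volumes.ndim == 4:
        volumes = volumes[None]
    if volumes.ndim != 5:
        raise ValueError(f"expected (n, C, D, H, W) volumes, got {volumes.shape}")
    out = _batched_forward(model, volumes, batch_size=batch_size)
    return out.reshape(-1)
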