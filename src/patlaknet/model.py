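"""Dilated residual network for direct Ki-map regression, and its training.

The architecture is a 2-D highres-net style regressor: 20 convolutional
layers (an initial 3x3 convolution, nine paired-convolution residual
blocks in pre-activation order BN -> ReLU -> conv, and a penultimate 1x1
feature-fusion convolution), followed by a 1x1 regression head to one
output channel.  The 3x3 layers use dilation 1 for the first seven,
2 for the next six and 4 for the last six, so the receptive field grows
without any pooling or striding and the output keeps the input's
spatial shape.  Training minimizes the L2 loss with Adam, a linear
learning-rate schedule from 3e-3 to 1e-4 and weight decay from 1e-5 to
0 over ten epochs, batch size 20, with 5% of samples held out for
monitoring -- mirroring the protocol of the study this package
replicates.  Prediction consumes normalized SUV/pass channels only; no
input function enters this path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nnet
from .patlak import ParametricMap
from .preprocess import (KI_KEY, InputConfig, NormalizationTable, channel_keys,
                         crop_center, denormalize, normalize)

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "HighResNet2D",
    "build_network",
    "train",
    "predict_ki",
    "save_model",
    "load_model",
    "TrainingDivergedError",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class NetworkSpec:
    """Layer plan: 7 undilated 3x3 layers, 6 at dilation 2, 6 at dilation 4."""

    n_initial_layers: int = 7
    n_mid_layers: int = 6
    n_late_layers: int = 6
    kernel: int = 3
    widths: tuple = (16, 32, 64)

    def __post_init__(self) -> None:
        if self.n_initial_layers < 3 or self.n_initial_layers % 2 == 0:
            raise ValueError("n_initial_layers must be odd (initial conv + paired blocks)")
        for n in (self.n_mid_layers, self.n_late_layers):
            if n < 2 or n % 2:
                raise ValueError("mid/late stages need an even layer count >= 2")
        if len(self.widths) != 3 or any(w < 1 for w in self.widths):
            raise ValueError("widths must be three positive stage widths")


class _ResBlock:
    """Pre-activation residual block: x + conv(relu(bn(conv(relu(bn(x)))))).

    A width increase across the block is carried by zero-padding the
    identity path with extra channels (parameter-free projection).
    """

    def __init__(self, in_c: int, out_c: int, dilation: int, rng):
        if out_c < in_c:
            raise ValueError("residual blocks may only keep or grow the width")
        self.bn1 = nnet.BatchNorm2d(in_c)
        self.relu1 = nnet.ReLU()
        self.conv1 = nnet.Conv2d(in_c, out_c, 3, dilation, rng)
        self.bn2 = nnet.BatchNorm2d(out_c)
        self.relu2 = nnet.ReLU()
        self.conv2 = nnet.Conv2d(out_c, out_c, 3, dilation, rng)
        # zero-init the residual branch's closing conv: the block starts as
        # the identity, which stabilizes and speeds up deep-residual training
        self.conv2.weight.value[...] = 0.0
        self.in_c, self.out_c = in_c, out_c

    @property
    def layers(self):
        return [self.bn1, self.relu1, self.conv1, self.bn2, self.relu2, self.conv2]

    def forward(self, x):
        h = self.conv1.forward(self.relu1.forward(self.bn1.forward(x)))
        h = self.conv2.forward(self.relu2.forward(self.bn2.forward(h)))
        if self.out_c != self.in_c:
            pad = np.zeros((x.shape[0], self.out_c - self.in_c, *x.shape[2:]),
                           dtype=x.dtype)
            skip = np.concatenate([x, pad], axis=1)
        else:
            skip = x
        return h + skip

    def backward(self, dout):
        dx_skip = dout[:, :self.in_c]
        dh = self.bn1.backward(self.relu1.backward(self.conv1.backward(
            self.bn2.backward(self.relu2.backward(self.conv2.backward(dout))))))
        return dh + dx_skip


class _Plain:
    """A non-residual layer chain (used for the stem and the head)."""

    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class HighResNet2D:
    """The assembled network; forward maps (N, C, H, W) -> (N, 1, H, W)."""

    def __init__(self, in_channels: int, spec: NetworkSpec = NetworkSpec(),
                 rng: np.random.Generator | None = None):
        if in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.spec = spec
        w1, w2, w3 = spec.widths
        units: list = [_Plain(nnet.Conv2d(in_channels, w1, 3, 1, rng))]
        for _ in range((spec.n_initial_layers - 1) // 2):
            units.append(_ResBlock(w1, w1, 1, rng))
        stage2 = [(w1, w2)] + [(w2, w2)] * (spec.n_mid_layers // 2 - 1)
        for ic, oc in stage2:
            units.append(_ResBlock(ic, oc, 2, rng))
        stage3 = [(w2, w3)] + [(w3, w3)] * (spec.n_late_layers // 2 - 1)
        for ic, oc in stage3:
            units.append(_ResBlock(ic, oc, 4, rng))
        self._fuse = nnet.Conv2d(w3, w3, 1, 1, rng)
        self._head = nnet.Conv2d(w3, 1, 1, 1, rng)
        units.append(_Plain(nnet.BatchNorm2d(w3), nnet.ReLU(), self._fuse,
                            nnet.BatchNorm2d(w3), nnet.ReLU(), self._head))
        self.units = units

    # -- introspection ------------------------------------------------------
    def _all_layers(self):
        return [layer for unit in self.units for layer in unit.layers]

    def conv_layers(self) -> list:
        """All convolutional layers excluding the 1x1 regression head."""
        return [l for l in self._all_layers()
                if isinstance(l, nnet.Conv2d) and l is not self._head]

    def layer_count(self) -> int:
        return len(self.conv_layers())

    def dilation_pattern(self) -> tuple:
        """Dilation factors of the spatial (3x3) convolutions, in order."""
        return tuple(l.dilation for l in self.conv_layers() if l.kernel == 3)

    def receptive_field(self) -> int:
        """Analytic receptive-field diameter: 1 + 2 * sum of 3x3 dilations."""
        return 1 + 2 * sum(self.dilation_pattern())

    def parameters(self):
        return [p for l in self._all_layers() for p in l.parameters()]

    # -- execution ----------------------------------------------------------
    def _set_training(self, flag: bool):
        for layer in self._all_layers():
            layer.training = flag

    def state(self) -> list:
        """Copies of all learnable parameters and BN running statistics."""
        out = []
        for layer in self._all_layers():
            for p in layer.parameters():
                out.append(p.value.copy())
            if isinstance(layer, nnet.BatchNorm2d):
                out.append(layer.running_mean.copy())
                out.append(layer.running_var.copy())
        return out

    def load_state(self, state: list) -> None:
        it = iter(state)
        for layer in self._all_layers():
            for p in layer.parameters():
                p.value = next(it).copy()
            if isinstance(layer, nnet.BatchNorm2d):
                layer.running_mean = next(it).copy()
                layer.running_var = next(it).copy()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected (N, {self.in_channels}, H, W) input, got {x.shape}")
        self._set_training(training)
        for unit in self.units:
            x = unit.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for unit in reversed(self.units):
            dout = unit.backward(dout)
        return dout


def build_network(spec: NetworkSpec = NetworkSpec(), in_channels: int = 1,
                  seed: int | None = None) -> HighResNet2D:
    if in_channels < 1:
        raise ValueError("in_channels must be >= 1")
    return HighResNet2D(in_channels, spec, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    optimizer: str = "adam"
    loss: str = "l2"
    lr_start: float = 3e-3
    lr_end: float = 1e-4
    weight_decay_start: float = 1e-5
    weight_decay_end: float = 0.0
    batch_size: int = 20
    samples_per_volume: int = 1
    epochs: int = 10
    holdout_fraction: float = 0.05
    seed: int = 0
    widths: tuple = (16, 32, 64)
    window_size: int | None = None  # train on random spatial windows of slices
    clip_grad_norm: float | None = 2.0  # rescale rare outlier gradient steps
    select_best: bool = True  # return the best-holdout-loss epoch checkpoint

    def __post_init__(self) -> None:
        if not (0.0 < self.holdout_fraction < 1.0):
            raise ValueError("holdout_fraction must be in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer != "adam" or self.loss != "l2":
            raise ValueError("only adam + L2 loss are supported")


def split_holdout(n_samples: int, fraction: float, rng) -> tuple:
    """Disjoint (train, holdout) index arrays; holdout gets >= 1 sample."""
    n_hold = max(1, int(round(fraction * n_samples)))
    if n_hold >= n_samples:
        raise ValueError("dataset too small to split a holdout set")
    perm = rng.permutation(n_samples)
    return perm[n_hold:], perm[:n_hold]


def train(dataset, cfg: TrainConfig, model: HighResNet2D | None = None,
          run_dir=None, n_steps: int | None = None):
    """Train on ``dataset = (X, y)``; returns ``(model, history)``.

    ``history`` maps epoch -> training and holdout L2 losses; a model
    checkpoint is written per epoch when ``run_dir`` is given.  Fully
    deterministic for a fixed seed and thread count.  ``n_steps`` caps
    the total number of optimizer steps (None = run all epochs).
    """
    X, y = dataset
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32)
    if len(X) == 0:
        raise ValueError("dataset is empty")
    if len(X) != len(y):
        raise ValueError("X and y sample counts differ")
    rng = np.random.default_rng(cfg.seed)
    if model is None:
        model = HighResNet2D(X.shape[1], NetworkSpec(widths=tuple(cfg.widths)), rng)
    train_idx, hold_idx = split_holdout(len(X), cfg.holdout_fraction, rng)
    opt = nnet.Adam(model.parameters())
    lrs = np.linspace(cfg.lr_start, cfg.lr_end, cfg.epochs)
    wds = np.linspace(cfg.weight_decay_start, cfg.weight_decay_end, cfg.epochs)
    history = {"train_loss": [], "holdout_loss": [], "train_idx": train_idx,
               "holdout_idx": hold_idx}
    steps_done = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            if n_steps is not None and steps_done >= n_steps:
                break
            batch = order[start:start + cfg.batch_size]
            xb, yb = X[batch], y[batch]
            ws = cfg.window_size
            if ws is not None and ws < X.shape[-1]:
                oy = rng.integers(0, X.shape[-2] - ws + 1, size=len(batch))
                ox = rng.integers(0, X.shape[-1] - ws + 1, size=len(batch))
                xb = np.stack([xb[b, :, oy[b]:oy[b] + ws, ox[b]:ox[b] + ws]
                               for b in range(len(batch))])
                yb = np.stack([yb[b, :, oy[b]:oy[b] + ws, ox[b]:ox[b] + ws]
                               for b in range(len(batch))])
            pred = model.forward(xb, training=True)
            diff = pred - yb
            loss = float(np.mean(diff.astype(np.float64) ** 2))
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, step {steps_done}")
            losses.append(loss)
            opt.zero_grad()
            model.backward((2.0 / diff.size) * diff)
            if cfg.clip_grad_norm is not None:
                params = model.parameters()
                gnorm = np.sqrt(sum(float((p.grad.astype(np.float64) ** 2).sum())
                                    for p in params))
                if gnorm > cfg.clip_grad_norm:
                    scale = np.float32(cfg.clip_grad_norm / gnorm)
                    for p in params:
                        p.grad *= scale
            opt.step(float(lrs[epoch]), float(wds[epoch]))
            steps_done += 1
        hold_pred = model.forward(X[hold_idx], training=False)
        hold_loss = float(np.mean((hold_pred - y[hold_idx]).astype(np.float64) ** 2))
        history["train_loss"].append(float(np.mean(losses)) if losses else np.nan)
        history["holdout_loss"].append(hold_loss)
        if cfg.select_best and hold_loss <= min(history["holdout_loss"]):
            best_state = model.state()
            history["best_epoch"] = epoch + 1
        if run_dir is not None:
            save_model(model, f"{run_dir}/checkpoint_epoch{epoch + 1:02d}.npz")
    if cfg.select_best:
        model.load_state(best_state)
    return model, history


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_ki(model: HighResNet2D, channels: dict, config: InputConfig,
               norm: NormalizationTable, target=None) -> ParametricMap:
    """Predict a denormalized Ki volume from SUV/pass channels.

    ``channels`` maps channel keys (``suv``, ``p13``, ...) to (S, H, W)
    volumes in SUV units.  The per-type factors in ``norm`` must be the
    ones used in training; the output is denormalized with the Ki
    factor.  No input function is consumed anywhere in this path.
    """
    keys = channel_keys(config)
    if config.channel_count != model.in_channels:
        raise ValueError(
            f"config {config.name!r} has {config.channel_count} channels but the "
            f"model expects {model.in_channels}")
    vols = []
    for k in keys:
        if k not in channels:
            raise KeyError(f"missing channel {k!r}")
        v = normalize(np.asarray(channels[k], dtype=np.float32), norm[k])
        vols.append(crop_center(v, target) if target is not None else v)
    x = np.stack(vols, axis=1)  # (S, C, H, W): slices as the batch
    pred = model.forward(x, training=False)[:, 0]
    ki = denormalize(pred.astype(np.float64), norm[KI_KEY])
    return ParametricMap(ki=ki, v=None, mask=np.ones(ki.shape, dtype=bool))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model: HighResNet2D, path) -> None:
    arrays = {}
    for i, layer in enumerate(model._all_layers()):
        for j, p in enumerate(layer.parameters()):
            arrays[f"param_{i}_{j}"] = p.value
        if isinstance(layer, nnet.BatchNorm2d):
            arrays[f"rmean_{i}"] = layer.running_mean
            arrays[f"rvar_{i}"] = layer.running_var
    spec = model.spec
    meta = np.array([model.in_channels, spec.n_initial_layers, spec.n_mid_layers,
                     spec.n_late_layers, *spec.widths], dtype=np.int64)
    np.savez(path, _meta=meta, **arrays)


def load_model(path) -> HighResNet2D:
    with np.load(path) as data:
        meta = data["_meta"]
        spec = NetworkSpec(n_initial_layers=int(meta[1]), n_mid_layers=int(meta[2]),
                           n_late_layers=int(meta[3]), widths=tuple(int(w) for w in meta[4:7]))
        model = HighResNet2D(int(meta[0]), spec, np.random.default_rng(0))
        for i, layer in enumerate(model._all_layers()):
            for j, p in enumerate(layer.parameters()):
                p.value = data[f"param_{i}_{j}"].copy()
                p.grad = np.zeros_like(p.value)
            if isinstance(layer, nnet.BatchNorm2d):
                layer.running_mean = data[f"rmean_{i}"].copy()
                layer.running_var = data[f"rvar_{i}"].copy()
    return model
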