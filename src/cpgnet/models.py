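"""Classifier architectures and training for methylation-status prediction.

Three 1-D convolutional classifiers operate on one-hot encoded windows:

* ``unet1d`` — an encoder (filters 16→32→64 with two ÷4 max-pools, e.g.
  length 299→74→18) and a decoder (transposed convolutions ×4, filters
  64→32→16, e.g. 18→72→288) joined by skip connections, followed by a
  global-average-pool / dense / softmax head over the two classes.
* ``cnn1d`` — a plain three-block convolutional baseline.
* ``mobilenet1d`` — a compact baseline built from inverted-residual blocks
  with depthwise-separable convolutions and squeeze-and-excitation gates.

Class order is fixed as (unmethylated, methylated); probability ties break
toward class index 0 (unmethylated).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .encoders import EncodedDataset
from .seqdata import CLASS_ORDER

ARCHITECTURES = ("unet1d", "cnn1d", "mobilenet1d")


def conv1d(signal: Sequence[float], kernel: Sequence[float]) -> np.ndarray:
    """Valid-mode 1-D sliding dot product F_i = sum_m I_{i+m} K_m.

    This is the cross-correlation orientation (no kernel flip), the form
    convolutional network layers actually compute.  Output length is
    n - k + 1.
    """
    signal = np.asarray(signal, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if signal.ndim != 1 or kernel.ndim != 1:
        raise ValueError("conv1d expects 1-D input and kernel")
    if len(kernel) == 0 or len(signal) < len(kernel):
        raise ValueError(
            f"kernel length {len(kernel)} incompatible with input length {len(signal)}"
        )
    return np.correlate(signal, kernel, mode="valid")


@dataclass
class ModelSpec:
    """Architecture hyper-parameters plus the derived length ladder."""

    architecture: str
    input_length: int
    input_channels: int
    encoder_filters: tuple[int, int, int] = (16, 32, 64)
    decoder_filters: tuple[int, int, int] = (64, 32, 16)
    pool_factor: int = 4
    kernel_size: int = 3
    class_order: tuple[str, str] = CLASS_ORDER
    encoder_lengths: tuple[int, ...] = field(default=())
    decoder_lengths: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        L, f = self.input_length, self.pool_factor
        l1, l2 = L // f, (L // f) // f
        if l2 < 1:
            raise ValueError(
                f"input length {L} too short for two ÷{f} pooling stages"
            )
        self.encoder_lengths = (L, l1, l2)
        self.decoder_lengths = (l2, l2 * f, l2 * f * f)


def build_unet(input_length: int, input_channels: int, **kw) -> ModelSpec:
    """UNet spec; for (299, 8) the ladder is 299→74→18 then 18→72→288."""
    return ModelSpec("unet1d", input_length, input_channels, **kw)


def build_cnn(input_length: int, input_channels: int, **kw) -> ModelSpec:
    """Three conv blocks (16/32/64 filters, ÷4 pools) with a softmax head."""
    return ModelSpec("cnn1d", input_length, input_channels, **kw)


def build_mobilenet1d(input_length: int, input_channels: int, **kw) -> ModelSpec:
    """Stem conv plus three inverted-residual blocks with SE gates."""
    return ModelSpec("mobilenet1d", input_length, input_channels, **kw)


@dataclass
class TrainingConfig:
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


class _Network:
    """Base: parameter collection and batched inference."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.length_ladder: list[int] = []

    def params(self) -> list[nn.Param]:
        raise NotImplementedError

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dlogits: np.ndarray) -> None:
        raise NotImplementedError


class UNet1D(_Network):
    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        super().__init__(spec)
        c = spec.input_channels
        k = spec.kernel_size
        f16, f32, f64 = spec.encoder_filters
        d64, d32, d16 = spec.decoder_filters
        self.enc1 = nn.conv_bn_relu(c, f16, k, rng)
        self.pool1 = nn.MaxPool1D(spec.pool_factor)
        self.enc2 = nn.conv_bn_relu(f16, f32, k, rng)
        self.pool2 = nn.MaxPool1D(spec.pool_factor)
        self.bottleneck = nn.conv_bn_relu(f32, f64, k, rng)
        self.up1 = nn.Sequential(
            nn.ConvTranspose1D(f64, d64, spec.pool_factor, rng),
            nn.BatchNorm1D(d64), nn.ReLU(),
        )
        self.up2 = nn.Sequential(
            nn.ConvTranspose1D(d64 + f32, d32, spec.pool_factor, rng),
            nn.BatchNorm1D(d32), nn.ReLU(),
        )
        self.dec3 = nn.conv_bn_relu(d32 + f16, d16, k, rng)
        self.gap = nn.GlobalAvgPool1D()
        self.head = nn.Dense(d16, 2, rng)

    def params(self):
        parts = (self.enc1, self.enc2, self.bottleneck, self.up1, self.up2,
                 self.dec3, self.head)
        return [p for part in parts for p in part.params()]

    def forward(self, x, train):
        e1 = self.enc1.forward(x, train)
        p1 = self.pool1.forward(e1, train)
        e2 = self.enc2.forward(p1, train)
        p2 = self.pool2.forward(e2, train)
        b = self.bottleneck.forward(p2, train)
        u1 = self.up1.forward(b, train)
        s2, self._off2 = nn.center_crop(e2, u1.shape[1])
        c1 = np.concatenate([u1, s2], axis=2)
        u2 = self.up2.forward(c1, train)
        s1, self._off1 = nn.center_crop(e1, u2.shape[1])
        c2 = np.concatenate([u2, s1], axis=2)
        d3 = self.dec3.forward(c2, train)
        self._shapes = (e1.shape, e2.shape, u1.shape[1], u2.shape[1])
        self.length_ladder = [x.shape[1], p1.shape[1], b.shape[1],
                              u1.shape[1], u2.shape[1]]
        g = self.gap.forward(d3, train)
        return self.head.forward(g, train)

    def backward(self, dlogits):
        e1_shape, e2_shape, len1, len2 = self._shapes
        d = self.gap.backward(self.head.backward(dlogits))
        dc2 = self.dec3.backward(d)
        n32 = self.spec.decoder_filters[1]
        du2, ds1 = dc2[:, :, :n32], dc2[:, :, n32:]
        dc1 = self.up2.backward(du2)
        n64 = self.spec.decoder_filters[0]
        du1, ds2 = dc1[:, :, :n64], dc1[:, :, n64:]
        db = self.up1.backward(du1)
        dp2 = self.bottleneck.backward(db)
        de2 = self.pool2.backward(dp2)
        de2_full = np.zeros(e2_shape)
        de2_full[:, self._off2 : self._off2 + len1, :] = ds2
        dp1 = self.enc2.backward(de2 + de2_full)
        de1 = self.pool1.backward(dp1)
        de1_full = np.zeros(e1_shape)
        de1_full[:, self._off1 : self._off1 + len2, :] = ds1
        self.enc1.backward(de1 + de1_full)


class CNN1D(_Network):
    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        super().__init__(spec)
        k, f = spec.kernel_size, spec.pool_factor
        filters = spec.encoder_filters
        cin = spec.input_channels
        layers: list[nn.Layer] = []
        length = spec.input_length
        for cout in filters:
            layers.append(nn.conv_bn_relu(cin, cout, k, rng))
            if length >= f:
                layers.append(nn.MaxPool1D(f))
                length //= f
            cin = cout
        self.body = nn.Sequential(*layers)
        self.gap = nn.GlobalAvgPool1D()
        self.head = nn.Dense(filters[-1], 2, rng)

    def params(self):
        return self.body.params() + self.head.params()

    def forward(self, x, train):
        y = x
        self.length_ladder = [x.shape[1]]
        for layer in self.body.layers:
            y = layer.forward(y, train)
            if isinstance(layer, nn.MaxPool1D):
                self.length_ladder.append(y.shape[1])
        g = self.gap.forward(y, train)
        return self.head.forward(g, train)

    def backward(self, dlogits):
        self.body.backward(self.gap.backward(self.head.backward(dlogits)))


class MobileNet1D(_Network):
    #: (out_channels, stride) for the three inverted-residual blocks
    BLOCKS = ((24, 2), (32, 2), (32, 1))

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        super().__init__(spec)
        stem_ch = spec.encoder_filters[0]
        self.stem = nn.conv_bn_relu(spec.input_channels, stem_ch, spec.kernel_size, rng)
        blocks = []
        cin = stem_ch
        for cout, stride in self.BLOCKS:
            blocks.append(nn.InvertedResidual(cin, cout, stride, rng))
            cin = cout
        self.blocks = blocks
        self.gap = nn.GlobalAvgPool1D()
        self.head = nn.Dense(cin, 2, rng)

    def params(self):
        out = self.stem.params()
        for b in self.blocks:
            out += b.params()
        return out + self.head.params()

    def forward(self, x, train):
        y = self.stem.forward(x, train)
        self.length_ladder = [y.shape[1]]
        for b in self.blocks:
            y = b.forward(y, train)
            self.length_ladder.append(y.shape[1])
        g = self.gap.forward(y, train)
        return self.head.forward(g, train)

    def backward(self, dlogits):
        dy = self.gap.backward(self.head.backward(dlogits))
        for b in reversed(self.blocks):
            dy = b.backward(dy)
        self.stem.backward(dy)


_NETWORKS = {"unet1d": UNet1D, "cnn1d": CNN1D, "mobilenet1d": MobileNet1D}


def instantiate(spec: ModelSpec, seed: int = 0) -> _Network:
    rng = np.random.default_rng(seed)
    return _NETWORKS[spec.architecture](spec, rng)


def count_parameters(spec_or_net: ModelSpec | _Network, seed: int = 0) -> int:
    net = (
        spec_or_net
        if isinstance(spec_or_net, _Network)
        else instantiate(spec_or_net, seed)
    )
    return sum(p.value.size for p in net.params())


@dataclass
class TrainedModel:
    spec: ModelSpec
    network: _Network
    config: TrainingConfig
    history: dict[str, list[float]]


def _batched_eval(net: _Network, x: np.ndarray, y: np.ndarray,
                  batch: int = 256) -> tuple[float, float]:
    """(accuracy, mean loss) in inference mode."""
    losses, correct = [], 0
    for i in range(0, len(x), batch):
        logits = net.forward(x[i : i + batch], train=False)
        loss, _ = nn.cross_entropy_grad(logits, y[i : i + batch])
        losses.append(loss * len(logits))
        correct += int((logits.argmax(axis=1) == y[i : i + batch]).sum())
    return correct / len(x), float(np.sum(losses) / len(x))


def train(
    spec: ModelSpec,
    train_set: EncodedDataset,
    val_set: EncodedDataset,
    config: TrainingConfig,
) -> TrainedModel:
    """Train for exactly ``config.epochs`` epochs (no early stopping).

    The seed fixes both weight initialization and batch order, so two runs
    with identical inputs produce identical histories on one platform.
    """
    for name, ds in (("train", train_set), ("val", val_set)):
        if ds.features.shape[1:] != (spec.input_length, spec.input_channels):
            raise ValueError(
                f"{name} set shape {ds.features.shape[1:]} does not match "
                f"spec ({spec.input_length}, {spec.input_channels})"
            )
    if len(np.unique(train_set.labels)) < 2:
        raise ValueError("training set must contain both classes")

    net = instantiate(spec, seed=config.seed)
    optimizer = nn.Adam(net.params(), lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(config.seed + 1)
    x_tr = train_set.features.astype(np.float64)
    y_tr = train_set.labels
    x_va = val_set.features.astype(np.float64)
    y_va = val_set.labels

    history: dict[str, list[float]] = {
        "train_acc": [], "val_acc": [], "train_loss": [], "val_loss": []
    }
    n = len(x_tr)
    for _ in range(config.epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss, epoch_correct = 0.0, 0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            optimizer.zero_grad()
            logits = net.forward(xb, train=True)
            loss, dlogits = nn.cross_entropy_grad(logits, yb)
            net.backward(dlogits)
            optimizer.step()
            epoch_loss += loss * len(idx)
            epoch_correct += int((logits.argmax(axis=1) == yb).sum())
        val_acc, val_loss = _batched_eval(net, x_va, y_va)
        history["train_acc"].append(epoch_correct / n)
        history["train_loss"].append(epoch_loss / n)
        history["val_acc"].append(val_acc)
        history["val_loss"].append(val_loss)
    return TrainedModel(spec=spec, network=net, config=config, history=history)


@dataclass
class Predictions:
    """Per-site class probabilities (CLASS_ORDER columns) and hard labels."""

    probabilities: np.ndarray
    label_indices: np.ndarray

    @property
    def labels(self) -> list[str]:
        return [CLASS_ORDER[i] for i in self.label_indices]

    @property
    def methylated_probability(self) -> np.ndarray:
        return self.probabilities[:, CLASS_ORDER.index("methylated")]


def predict(model: TrainedModel, data: EncodedDataset, batch: int = 256) -> Predictions:
    """Softmax probabilities and argmax labels (ties toward unmethylated)."""
    spec = model.spec
    if data.features.shape[1:] != (spec.input_length, spec.input_channels):
        raise ValueError(
            f"data shape {data.features.shape[1:]} does not match spec "
            f"({spec.input_length}, {spec.input_channels})"
        )
    probs = []
    x = data.features.astype(np.float64)
    for i in range(0, len(x), batch):
        logits = model.network.forward(x[i : i + batch], train=False)
        probs.append(nn.softmax(logits))
    p = np.concatenate(probs)
    return Predictions(probabilities=p, label_indices=p.argmax(axis=1))


def write_history(history: dict[str, list[float]], path: str | Path) -> None:
    """Per-epoch TSV: epoch  train_acc  val_acc  train_loss  val_loss."""
    with open(path, "w") as fh:
        fh.write("epoch\ttrain_acc\tval_acc\ttrain_loss\tval_loss\n")
        for e in range(len(history["train_acc"])):
            fh.write(
                f"{e + 1}\t{history['train_acc'][e]:.6f}\t{history['val_acc'][e]:.6f}"
                f"\t{history['train_loss'][e]:.6f}\t{history['val_loss'][e]:.6f}\n"
            )


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Checkpoint: weights (.npz) plus a self-describing JSON manifest."""
    path = Path(path)
    arrays = {f"p{i}": p.value for i, p in enumerate(model.network.params())}
    # batch-norm running stats are state, not parameters, but must persist
    bn_stats = {}
    for i, layer in enumerate(_iter_layers(model.network)):
        if isinstance(layer, nn.BatchNorm1D):
            bn_stats[f"bn{i}_mean"] = layer.running_mean
            bn_stats[f"bn{i}_var"] = layer.running_var
    np.savez_compressed(path, **arrays, **bn_stats)
    manifest = {
        "architecture": model.spec.architecture,
        "input_length": model.spec.input_length,
        "input_channels": model.spec.input_channels,
        "class_order": list(model.spec.class_order),
        "training": asdict(model.config),
        "history": model.history,
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    npz = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with open(npz.with_suffix(".json")) as fh:
        manifest = json.load(fh)
    spec = ModelSpec(
        architecture=manifest["architecture"],
        input_length=manifest["input_length"],
        input_channels=manifest["input_channels"],
    )
    config = TrainingConfig(**manifest["training"])
    net = instantiate(spec, seed=config.seed)
    arrays = np.load(npz)
    for i, p in enumerate(net.params()):
        p.value[...] = arrays[f"p{i}"]
    for i, layer in enumerate(_iter_layers(net)):
        if isinstance(layer, nn.BatchNorm1D):
            layer.running_mean[...] = arrays[f"bn{i}_mean"]
            layer.running_var[...] = arrays[f"bn{i}_var"]
    return TrainedModel(spec=spec, network=net, config=config,
                        history=manifest["history"])


def _iter_layers(net: _Network):
    """Deterministic depth-first walk over all leaf layers of a network."""
    def walk(obj):
        if isinstance(obj, nn.Sequential):
            for sub in obj.layers:
                yield from walk(sub)
        elif isinstance(obj, nn.InvertedResidual):
            for sub in (obj.expand, obj.depthwise, obj.dw_bn_relu, obj.se, obj.project):
                yield from walk(sub)
        elif isinstance(obj, nn.Layer):
            yield obj

    if isinstance(net, UNet1D):
        parts = (net.enc1, net.pool1, net.enc2, net.pool2, net.bottleneck,
                 net.up1, net.up2, net.dec3, net.gap, net.head)
    elif isinstance(net, CNN1D):
        parts = (net.body, net.gap, net.head)
    else:
        parts = (net.stem, *net.blocks, net.gap, net.head)
    for part in parts:
        yield from walk(part)
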