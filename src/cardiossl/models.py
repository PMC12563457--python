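"""Declarative network specifications and the build/transfer machinery.

Three architectures cover the study:

* a four-block CNN encoder (conv 32/64/128/256, 3x3, ReLU, 2x2 max-pool,
  then dense 256/128 and a sigmoid scalar) used by the binary pretexts;
* a mirrored convolutional autoencoder (conv 32/64/128 with batch norm,
  LeakyReLU and max-pooling; decoder with nearest up-sampling) for the
  generative pretext;
* the encoder trunk plus a two-layer projection head with L2-normalized
  output for the contrastive pretext.

Downstream transfer removes only the pretext output layer (for the
autoencoder, the whole decoder), keeps the pretrained weights bit-for-bit,
and appends dense(256) -> dropout(0.5) -> dense(128) -> sigmoid.
"""

from __future__ import annotations

import copy
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn

__all__ = [
    "ConvBlock",
    "NetworkSpec",
    "BuiltModel",
    "encoder_spec",
    "autoencoder_spec",
    "alexnet_style_spec",
    "build_model",
    "transfer_surgery",
    "simclr_model",
    "count_parameters",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ConvBlock:
    filters: int
    kernel: int = 3
    activation: str = "relu"       # relu | leaky_relu | sigmoid | linear
    batch_norm: bool = False
    pool: str = "none"             # max2 | up2 | none


@dataclass(frozen=True)
class NetworkSpec:
    """Layer-stack description; ``output`` is one of ``sigmoid_scalar``,
    ``image_sigmoid`` or ``embedding`` (with ``embedding_dim``)."""

    input_shape: tuple[int, int, int]
    conv_blocks: tuple[ConvBlock, ...]
    dense_units: tuple[int, ...] = ()
    dropout_rate: float = 0.0
    output: str = "sigmoid_scalar"
    embedding_dim: int = 0

    def __post_init__(self):
        h, w, _ = self.input_shape
        n_pool = sum(1 for b in self.conv_blocks if b.pool == "max2")
        if h % (2 ** n_pool) or w % (2 ** n_pool):
            raise ValueError(
                f"input {h}x{w} not divisible by 2^{n_pool} pooling stages")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.output not in ("sigmoid_scalar", "image_sigmoid", "embedding"):
            raise ValueError(f"unknown output kind {self.output!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        blocks = tuple(ConvBlock(**b) for b in d["conv_blocks"])
        return cls(input_shape=tuple(d["input_shape"]), conv_blocks=blocks,
                   dense_units=tuple(d.get("dense_units", ())),
                   dropout_rate=d.get("dropout_rate", 0.0),
                   output=d.get("output", "sigmoid_scalar"),
                   embedding_dim=d.get("embedding_dim", 0))

    def to_yaml(self) -> str:
        import yaml

        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "NetworkSpec":
        import yaml

        return cls.from_dict(yaml.safe_load(text))


def encoder_spec(input_shape: tuple[int, int, int] = (180, 180, 3),
                 filters: tuple[int, ...] = (32, 64, 128, 256),
                 dense_units: tuple[int, ...] = (256, 128)) -> NetworkSpec:
    """Four-block CNN classifier for the binary pretexts."""
    h, w, _ = input_shape
    if h != w or h % 16:
        raise ValueError(f"encoder input must be square and divisible by 16, "
                         f"got {h}x{w}")
    blocks = tuple(ConvBlock(f, 3, "relu", False, "max2") for f in filters)
    return NetworkSpec(input_shape, blocks, dense_units, 0.0, "sigmoid_scalar")


def autoencoder_spec(input_shape: tuple[int, int, int]) -> NetworkSpec:
    """Mirrored convolutional autoencoder for the generative pretext."""
    h, w, c = input_shape
    if h != w or h % 8:
        raise ValueError(f"autoencoder input must be square and divisible "
                         f"by 8, got {h}x{w}")
    enc = tuple(ConvBlock(f, 3, "leaky_relu", True, "max2")
                for f in (32, 64, 128))
    dec = tuple(ConvBlock(f, 3, "leaky_relu", True, "up2")
                for f in (128, 64, 32))
    final = (ConvBlock(c, 3, "sigmoid", False, "none"),)
    return NetworkSpec(input_shape, enc + dec + final, (), 0.0, "image_sigmoid")


def alexnet_style_spec(input_shape: tuple[int, int, int]) -> NetworkSpec:
    """Larger five-block trunk (AlexNet-like depth progression); optional
    alternative contrastive encoder, not used by the default pipelines."""
    h, w, _ = input_shape
    if h != w or h % 32:
        raise ValueError("alexnet-style input must be square, divisible by 32")
    blocks = tuple(ConvBlock(f, 3, "relu", False, "max2")
                   for f in (64, 128, 192, 192, 128))
    return NetworkSpec(input_shape, blocks, (512, 256), 0.0, "sigmoid_scalar")


@dataclass
class BuiltModel:
    """A built network plus the description it was built from."""

    net: nn.Sequential
    spec: dict
    seed: int
    input_shape: tuple[int, int, int]
    kind: str  # binary | autoencoder | embedding

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Inference-mode forward pass; scalar outputs are squeezed."""
        outs = []
        for i in range(0, len(x), batch_size):
            out = self.net.forward(np.asarray(x[i:i + batch_size],
                                              dtype=np.float32), train=False)
            outs.append(out)
        if not outs:
            return np.empty(0)
        out = np.concatenate(outs)
        return out[:, 0] if self.kind == "binary" else out

    def input_gradient(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Gradient of the mean BCE loss with respect to the input pixels.

        The sigmoid output is fused with the cross-entropy derivative
        ((p - y)/N), so the gradient is exact even for saturated outputs.
        """
        if self.kind != "binary":
            raise ValueError("input gradients are defined for binary models")
        x = np.asarray(x, dtype=np.float32)
        p = self.net.forward(x, train=False)[:, 0]
        delta = ((p - np.asarray(y, dtype=np.float64)) / len(x)).astype(p.dtype)
        self.net.zero_grad()
        grad = self.net.backward(delta[:, None], start=-2)
        if not np.isfinite(grad).all():
            raise FloatingPointError("non-finite input gradient")
        return grad

    def checksum(self) -> str:
        return self.net.checksum()

    def clone(self) -> "BuiltModel":
        return BuiltModel(copy.deepcopy(self.net), copy.deepcopy(self.spec),
                          self.seed, self.input_shape, self.kind)


_ACT = {"relu": nn.ReLU, "leaky_relu": nn.LeakyReLU, "sigmoid": nn.Sigmoid}


def _conv_layers(blocks, c_in, rng, dtype):
    layers, c = [], c_in
    for i, b in enumerate(blocks):
        layers.append(nn.Conv2D(c, b.filters, b.kernel, rng=rng, dtype=dtype,
                                name=f"conv{i}"))
        if b.batch_norm:
            layers.append(nn.BatchNorm(b.filters, dtype=dtype, name=f"bn{i}"))
        if b.activation != "linear":
            layers.append(_ACT[b.activation]())
        if b.pool == "max2":
            layers.append(nn.MaxPool2())
        elif b.pool == "up2":
            layers.append(nn.UpSample2())
        c = b.filters
    return layers, c


def _trunk_feature_dim(spec: NetworkSpec) -> int:
    h = spec.input_shape[0]
    c = spec.input_shape[2]
    for b in spec.conv_blocks:
        c = b.filters
        if b.pool == "max2":
            h //= 2
        elif b.pool == "up2":
            h *= 2
    return h * h * c


def build_model(spec: NetworkSpec, seed: int = 0,
                dtype=np.float32) -> BuiltModel:
    """Deterministically initialize a network from its specification."""
    rng = np.random.default_rng(seed)
    layers, c = _conv_layers(spec.conv_blocks, spec.input_shape[2], rng, dtype)
    if spec.output == "image_sigmoid":
        return BuiltModel(nn.Sequential(layers), spec.to_dict(), seed,
                          spec.input_shape, "autoencoder")
    layers.append(nn.Flatten())
    d = _trunk_feature_dim(spec)
    for j, units in enumerate(spec.dense_units):
        layers.append(nn.Dense(d, units, rng=rng, dtype=dtype, name=f"dense{j}"))
        layers.append(nn.ReLU())
        if spec.dropout_rate > 0:
            layers.append(nn.Dropout(spec.dropout_rate))
        d = units
    if spec.output == "embedding":
        layers.append(nn.Dense(d, spec.embedding_dim, rng=rng, dtype=dtype,
                               name="proj"))
        layers.append(nn.L2Normalize())
        return BuiltModel(nn.Sequential(layers), spec.to_dict(), seed,
                          spec.input_shape, "embedding")
    layers.append(nn.Dense(d, 1, rng=rng, dtype=dtype, name="out"))
    layers.append(nn.Sigmoid())
    return BuiltModel(nn.Sequential(layers), spec.to_dict(), seed,
                      spec.input_shape, "binary")


def _encoder_trunk(model: BuiltModel) -> list[nn.Layer]:
    """Copy of the model's layers with the pretext output removed."""
    layers = model.net.layers
    if model.kind == "binary":
        # drop the final Dense(1) + Sigmoid
        if len(layers) < 2 or not isinstance(layers[-1], nn.Sigmoid) \
                or not isinstance(layers[-2], nn.Dense):
            raise ValueError("no identifiable sigmoid output layer")
        return copy.deepcopy(layers[:-2])
    if model.kind == "embedding":
        # drop projection head: Dense + L2Normalize
        if not isinstance(layers[-1], nn.L2Normalize):
            raise ValueError("no identifiable projection output")
        return copy.deepcopy(layers[:-2])
    if model.kind == "autoencoder":
        # keep the encoder half: everything up to and including the last
        # max-pool before the first up-sampling stage; then flatten.
        first_up = next((i for i, l in enumerate(layers)
                         if isinstance(l, nn.UpSample2)), None)
        if first_up is None:
            raise ValueError("autoencoder has no decoder to discard")
        cut = first_up - 1
        while cut >= 0 and not isinstance(layers[cut], nn.MaxPool2):
            cut -= 1
        if cut < 0:
            raise ValueError("no pooling bottleneck found")
        trunk = copy.deepcopy(layers[:cut + 1])
        trunk.append(nn.Flatten())
        return trunk
    raise ValueError(f"unknown model kind {model.kind!r}")


def _trunk_out_dim(trunk: list[nn.Layer], input_shape) -> int:
    x = np.zeros((1, *input_shape), dtype=np.float32)
    for layer in trunk:
        x = layer.forward(x, train=False)
    return x.shape[1]


def transfer_surgery(pretext_model: BuiltModel,
                     head_units: tuple[int, int] = (256, 128),
                     dropout_rate: float = 0.5,
                     seed: int = 0) -> BuiltModel:
    """Downstream classifier from a pretrained pretext model.

    The retained trunk carries the pretext weights unchanged; the new head
    is dense(head_units[0]) -> dropout -> dense(head_units[1]) -> sigmoid
    scalar, freshly initialized from ``seed``.
    """
    trunk = _encoder_trunk(pretext_model)
    d = _trunk_out_dim(trunk, pretext_model.input_shape)
    rng = np.random.default_rng(seed)
    dtype = trunk_dtype(trunk)
    head = [
        nn.Dense(d, head_units[0], rng=rng, dtype=dtype, name="head0"),
        nn.ReLU(),
        nn.Dropout(dropout_rate),
        nn.Dense(head_units[0], head_units[1], rng=rng, dtype=dtype,
                 name="head1"),
        nn.ReLU(),
        nn.Dense(head_units[1], 1, rng=rng, dtype=dtype, name="head_out"),
        nn.Sigmoid(),
    ]
    spec = {"surgery_from": pretext_model.spec, "head_units": list(head_units),
            "dropout_rate": dropout_rate}
    return BuiltModel(nn.Sequential(trunk + head), spec, seed,
                      pretext_model.input_shape, "binary")


def trunk_dtype(trunk: list[nn.Layer]) -> np.dtype:
    for layer in trunk:
        for p in layer.params():
            return p.value.dtype
    return np.dtype(np.float32)


def simclr_model(encoder: NetworkSpec, proj_dim: int = 128,
                 seed: int = 0, dtype=np.float32) -> BuiltModel:
    """Shared encoder trunk plus a 2-layer projection head, unit-norm output."""
    base = build_model(encoder, seed=seed, dtype=dtype)
    trunk = _encoder_trunk(base)
    d = _trunk_out_dim(trunk, base.input_shape)
    rng = np.random.default_rng(seed + 1)
    head = [
        nn.Dense(d, d, rng=rng, dtype=dtype, name="proj0"),
        nn.ReLU(),
        nn.Dense(d, proj_dim, rng=rng, dtype=dtype, name="proj1"),
        nn.L2Normalize(),
    ]
    spec = {"simclr_encoder": encoder.to_dict(), "proj_dim": proj_dim}
    return BuiltModel(nn.Sequential(trunk + head), spec, seed,
                      base.input_shape, "embedding")


def count_parameters(model: BuiltModel) -> tuple[int, int]:
    """(total, trainable) parameter counts from the weight collection."""
    total = sum(p.size for p in model.net.params())
    trainable = sum(p.size for p in model.net.params() if p.trainable)
    return total, trainable


def save_model(model: BuiltModel, path: str | os.PathLike) -> None:
    """Weights as .npz plus a JSON sidecar (spec, seed, checksum)."""
    path = os.fspath(path)
    weights = {f"w{i}": p.value for i, p in enumerate(model.net.params())}
    np.savez(path if path.endswith(".npz") else path + ".npz", **weights)
    sidecar = {"spec": model.spec, "seed": model.seed,
               "input_shape": list(model.input_shape), "kind": model.kind,
               "checksum": model.checksum()}
    with open(os.path.splitext(path)[0] + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)


def load_model(path: str | os.PathLike, builder) -> BuiltModel:
    """Rebuild via ``builder(sidecar_spec_dict)`` and restore the weights."""
    path = os.fspath(path)
    base = os.path.splitext(path)[0]
    with open(base + ".json") as fh:
        sidecar = json.load(fh)
    model = builder(sidecar)
    data = np.load(base + ".npz")
    model.net.set_weights([data[f"w{i}"] for i in range(len(data.files))])
    if model.checksum() != sidecar["checksum"]:
        raise ValueError("weight checksum mismatch after load")
    return model
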