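"""Encoders f(.) mapping 30-element pose vectors to latent representations h.

Two families are provided:

* residual convolutional encoders (``resnet18`` / ``resnet50`` style basic and
  bottleneck blocks) whose first convolution takes a single-channel input:
  the 30-vector arranged as a 1 x 10 x 3 grid (landmarks x coordinates).
  Because that grid is tiny, the stem uses a 3x3 / stride-1 / pad-1
  convolution with no initial pooling, and global average pooling absorbs
  the final feature map.
* an ``mlp`` encoder (30 -> 256 -> 256 -> repr_dim, ReLU) — a lightweight
  convenience for desk-scale experiments, not a residual network.

``adapt_first_conv`` folds pretrained RGB first-layer kernels into a
single-channel kernel by channel averaging, for when externally pretrained
weights are supplied.  No weights are downloaded by this package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from ._autograd import Tensor
from .landmarks import FEATURE_DIM

__all__ = [
    "EncoderConfig",
    "reshape_input",
    "build_encoder",
    "encode",
    "set_input_standardizer",
    "apply_input_standardizer",
    "adapt_first_conv",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_FORMAT_VERSION = 1

_DEFAULT_REPR_DIM = {"resnet18": 512, "resnet50": 2048, "mlp": 128}


@dataclass(frozen=True)
class EncoderConfig:
    kind: str = "mlp"
    input_layout: tuple[int, int] = (10, 3)
    pretrained_init: bool = False
    repr_dim: int | None = None
    mlp_hidden: int = 256

    def __post_init__(self):
        if self.kind not in _DEFAULT_REPR_DIM:
            raise ValueError(f"unknown encoder kind {self.kind!r}")
        if int(np.prod(self.input_layout)) != FEATURE_DIM:
            raise ValueError(f"input_layout {self.input_layout} does not tile {FEATURE_DIM}")
        if self.repr_dim is not None and self.repr_dim <= 0:
            raise ValueError("repr_dim must be positive")

    @property
    def output_dim(self) -> int:
        if self.kind == "mlp" and self.repr_dim is not None:
            return self.repr_dim
        return _DEFAULT_REPR_DIM[self.kind]


def reshape_input(v: np.ndarray, layout: tuple[int, int] = (10, 3)) -> np.ndarray:
    """Arrange 30-vectors as single-channel grids.

    Row j of the default 10 x 3 grid holds the (x, y, z) triplet of landmark
    j, preserving landmark locality along the row axis.  Accepts a single
    vector or a batch; flattening the grid recovers the vector exactly.
    """
    v = np.asarray(v, dtype=np.float64)
    if int(np.prod(layout)) != FEATURE_DIM:
        raise ValueError(f"layout {layout} incompatible with {FEATURE_DIM}-vectors")
    if v.ndim == 1:
        if v.shape[0] != FEATURE_DIM:
            raise ValueError(f"expected length-{FEATURE_DIM} vector")
        return v.reshape(1, *layout)
    if v.ndim == 2 and v.shape[1] == FEATURE_DIM:
        return v.reshape(v.shape[0], 1, *layout)
    raise ValueError(f"cannot reshape array of shape {v.shape}")


class MLPEncoder(nn.Module):
    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        h = config.mlp_hidden
        self.net = nn.Sequential(
            nn.Linear(FEATURE_DIM, h, rng),
            nn.ReLU(),
            nn.Linear(h, h, rng),
            nn.ReLU(),
            nn.Linear(h, config.output_dim, rng),
        )
        self.config = config
        self.input_mean: np.ndarray | None = None
        self.input_std: np.ndarray | None = None

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


def _basic_block(cin: int, cout: int, stride: int, rng) -> nn.Module:
    body = nn.Sequential(
        nn.Conv2d(cin, cout, 3, rng, stride=stride, padding=1),
        nn.ReLU(),
        nn.Conv2d(cout, cout, 3, rng, stride=1, padding=1),
    )
    shortcut = None
    if stride != 1 or cin != cout:
        shortcut = nn.Conv2d(cin, cout, 1, rng, stride=stride, padding=0)
    return nn.Residual(body, shortcut)


def _bottleneck_block(cin: int, cmid: int, stride: int, rng) -> nn.Module:
    cout = 4 * cmid
    body = nn.Sequential(
        nn.Conv2d(cin, cmid, 1, rng),
        nn.ReLU(),
        nn.Conv2d(cmid, cmid, 3, rng, stride=stride, padding=1),
        nn.ReLU(),
        nn.Conv2d(cmid, cout, 1, rng),
    )
    shortcut = None
    if stride != 1 or cin != cout:
        shortcut = nn.Conv2d(cin, cout, 1, rng, stride=stride, padding=0)
    return nn.Residual(body, shortcut)


class ResNetEncoder(nn.Module):
    """Residual conv encoder on the 1 x 10 x 3 landmark grid."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        depths = {"resnet18": (2, 2, 2, 2), "resnet50": (3, 4, 6, 3)}[config.kind]
        bottleneck = config.kind == "resnet50"
        widths = (64, 128, 256, 512)
        self.stem = nn.Conv2d(1, 64, 3, rng, stride=1, padding=1)
        blocks: list[nn.Module] = []
        cin = 64
        for stage, (width, depth) in enumerate(zip(widths, depths)):
            for i in range(depth):
                stride = 2 if (stage > 0 and i == 0) else 1
                if bottleneck:
                    blocks.append(_bottleneck_block(cin, width, stride, rng))
                    cin = 4 * width
                else:
                    blocks.append(_basic_block(cin, width, stride, rng))
                    cin = width
        self.blocks = blocks
        self.config = config
        self.input_mean: np.ndarray | None = None
        self.input_std: np.ndarray | None = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.stem(x).relu()
        for block in self.blocks:
            out = block(out)
        # global average pooling over the remaining spatial extent
        return out.mean(axis=3).mean(axis=2)


def build_encoder(config: EncoderConfig, rng: np.random.Generator) -> nn.Module:
    """Instantiate a randomly initialized encoder for the given config.

    With ``pretrained_init=True`` no weight source is bundled, so a clear
    error directs the caller either to supply adapted weights via
    ``adapt_first_conv`` + ``load_state_arrays`` or to use random init.
    """
    if config.pretrained_init:
        raise ValueError(
            "no pretrained weights are bundled; load externally adapted weights "
            "(see adapt_first_conv) or set pretrained_init=False for random init"
        )
    if config.kind == "mlp":
        return MLPEncoder(config, rng)
    return ResNetEncoder(config, rng)


def set_input_standardizer(encoder: nn.Module, data: np.ndarray) -> None:
    """Fit the encoder's fixed input standardization from a data matrix.

    Contrastive pretraining fits per-coordinate mean/std on its (unlabeled)
    training matrix and stores them on the encoder — the analogue of the
    dataset-statistics input normalization bundled with pretrained image
    backbones.  The statistics are frozen into the checkpoint; encoders that
    never went through pretraining keep the identity transform.
    """
    data = np.asarray(data, dtype=np.float64)
    std = data.std(axis=0)
    encoder.input_mean = data.mean(axis=0)
    encoder.input_std = np.where(std > 1e-8, std, 1.0)


def apply_input_standardizer(encoder: nn.Module, x: np.ndarray) -> np.ndarray:
    if getattr(encoder, "input_mean", None) is None:
        return x
    return (x - encoder.input_mean) / encoder.input_std


def encode(encoder: nn.Module, x: np.ndarray, layout: tuple[int, int] = (10, 3)) -> np.ndarray:
    """Run the encoder on a vector or batch of vectors, returning h.

    Inference is deterministic (no stochastic layers); a batched call equals
    stacked per-sample calls up to floating-point reduction order.
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.isfinite(x).all():
        raise ValueError("encoder input must be finite")
    single = x.ndim == 1
    batch = x[None, :] if single else x
    batch = apply_input_standardizer(encoder, batch)
    if isinstance(encoder, MLPEncoder):
        out = encoder(Tensor(batch)).data
    else:
        out = encoder(Tensor(reshape_input(batch, layout))).data
    return out[0] if single else out


def adapt_first_conv(pretrained_weights: np.ndarray) -> np.ndarray:
    """Collapse a pretrained 3-channel first-conv kernel to single channel.

    The single-channel kernel is the channel mean of the RGB kernel; all
    other layers of a pretrained network are taken as-is.
    """
    w = np.asarray(pretrained_weights, dtype=np.float64)
    if w.ndim != 4 or w.shape[1] != 3:
        raise ValueError(f"expected (out, 3, kh, kw) kernel, got {w.shape}")
    return w.mean(axis=1, keepdims=True)


# -- checkpoints --------------------------------------------------------------


def save_checkpoint(
    encoder: nn.Module, config: EncoderConfig, path: str | Path, extra: dict | None = None
) -> None:
    """Single-file NPZ checkpoint with a versioned JSON header."""
    header = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "kind": config.kind,
        "input_layout": list(config.input_layout),
        "repr_dim": config.output_dim,
        "mlp_hidden": config.mlp_hidden,
        "extra": extra or {},
    }
    arrays = {f"param_{i:04d}": a for i, a in enumerate(encoder.state_arrays())}
    if getattr(encoder, "input_mean", None) is not None:
        arrays["input_mean"] = encoder.input_mean
        arrays["input_std"] = encoder.input_std
    np.savez(path, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[nn.Module, EncoderConfig, dict]:
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        if header["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint version {header['format_version']}")
        config = EncoderConfig(
            kind=header["kind"],
            input_layout=tuple(header["input_layout"]),
            repr_dim=header["repr_dim"] if header["kind"] == "mlp" else None,
            mlp_hidden=header["mlp_hidden"],
        )
        encoder = build_encoder(config, np.random.default_rng(0))
        arrays = [data[k] for k in sorted(k for k in data.files if k.startswith("param_"))]
        encoder.load_state_arrays(arrays)
        if "input_mean" in data.files:
            encoder.input_mean = data["input_mean"]
            encoder.input_std = data["input_std"]
    return encoder, config, header.get("extra", {})
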