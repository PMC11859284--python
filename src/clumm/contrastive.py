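"""Contrastive pretraining: projector head, NT-Xent loss, training loop.

A batch of b source rows yields 2b views (each row jittered and scaled).
For anchor i the normalized temperature-scaled cross entropy (NT-Xent)
compares the positive pair's cosine similarity against all 2b - 1 other
views:

    L_i = -log [ exp(cos(psi_i, psi_pos(i)) / tau)
                 / sum_{k != i} exp(cos(psi_i, psi_k) / tau) ]

The batch objective averages L_i over all 2b anchors (both orderings of
every pair).  After training the projector g is discarded and only the
encoder f is kept.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from ._autograd import Tensor, concat
from .augment import AugmentConfig, augment_batch
from .encoder import (
    EncoderConfig,
    MLPEncoder,
    apply_input_standardizer,
    build_encoder,
    reshape_input,
    set_input_standardizer,
)
from .landmarks import FeatureMatrix
from .optim import AdamW, cosine_schedule

logger = logging.getLogger(__name__)

__all__ = [
    "ProjectorConfig",
    "NTXentConfig",
    "PretrainConfig",
    "Projector",
    "project",
    "cosine_similarity",
    "nt_xent_loss",
    "pretrain",
    "PretrainResult",
]


@dataclass(frozen=True)
class ProjectorConfig:
    """g(.): linear -> ReLU -> linear, mapping h into the contrastive space."""

    hidden_dim: int | None = None  # defaults to the encoder repr_dim
    out_dim: int = 128

    def __post_init__(self):
        if self.out_dim <= 0:
            raise ValueError("out_dim must be positive")


@dataclass(frozen=True)
class NTXentConfig:
    temperature: float = 0.5

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


@dataclass(frozen=True)
class PretrainConfig:
    epochs: int = 500
    batch_size: int = 64
    learning_rate: float = 0.005
    weight_decay: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.epochs <= 0 or self.batch_size < 2:
            raise ValueError("epochs must be positive and batch_size >= 2")


class Projector(nn.Module):
    def __init__(self, in_dim: int, config: ProjectorConfig, rng: np.random.Generator):
        hidden = config.hidden_dim or in_dim
        self.net = nn.Sequential(
            nn.Linear(in_dim, hidden, rng),
            nn.ReLU(),
            nn.Linear(hidden, config.out_dim, rng),
        )

    def forward(self, h: Tensor) -> Tensor:
        return self.net(h)


def project(projector: Projector, h: np.ndarray) -> np.ndarray:
    """Apply the projector head to representations (vector or batch)."""
    h = np.asarray(h, dtype=np.float64)
    single = h.ndim == 1
    out = projector(Tensor(h[None, :] if single else h)).data
    return out[0] if single else out


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """cos(u, v) in [-1, 1]; zero-norm inputs map to 0 by convention."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        warnings.warn("cosine similarity of a zero vector defined as 0", stacklevel=2)
        return 0.0
    return float(u @ v / (nu * nv))


def _normalize_rows(z: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(z, axis=1, keepdims=True)
    out = np.divide(z, norms, out=np.zeros_like(z), where=norms > 0)
    if (norms == 0).any():
        warnings.warn("zero-vector projection: cosine similarities set to 0", stacklevel=3)
    return out


def anchor_terms(
    z1: np.ndarray, z2: np.ndarray, temperature: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-anchor (log-denominator, positive-logit) pairs of NT-Xent.

    Views are stacked as [z1; z2]; anchor i's positive sits at (i + b) mod 2b.
    The log-denominator is the log-sum-exp over the 2b - 1 non-self logits.
    """
    z1 = np.atleast_2d(np.asarray(z1, dtype=np.float64))
    z2 = np.atleast_2d(np.asarray(z2, dtype=np.float64))
    if z1.shape != z2.shape:
        raise ValueError("view batches must have identical shapes")
    b = z1.shape[0]
    if b < 1:
        raise ValueError("batch must contain at least one pair")
    zn = _normalize_rows(np.vstack([z1, z2]))
    logits = zn @ zn.T / temperature
    np.fill_diagonal(logits, -np.inf)  # exclude k = i (self)
    pos_idx = (np.arange(2 * b) + b) % (2 * b)
    pos = logits[np.arange(2 * b), pos_idx]
    rowmax = logits.max(axis=1)
    lse = np.log(np.exp(logits - rowmax[:, None]).sum(axis=1)) + rowmax
    return lse, pos


def nt_xent_loss(z1: np.ndarray, z2: np.ndarray, temperature: float = 0.5) -> float:
    """Batch-mean NT-Xent over all 2b anchors.

    With b = 1 the only non-self view is the positive itself, so the loss is
    identically 0; with all projections identical it equals log(2b - 1).
    """
    lse, pos = anchor_terms(z1, z2, temperature)
    return float(np.mean(lse - pos))


def _nt_xent_tensor(p1: Tensor, p2: Tensor, temperature: float) -> Tensor:
    """Differentiable NT-Xent used by the training loop (epsilon-guarded norms)."""
    z = concat([p1, p2], axis=0)
    b2 = z.shape[0]
    b = b2 // 2
    norms = ((z * z).sum(axis=1, keepdims=True) + 1e-24).sqrt()
    zn = z / norms
    logits = (zn @ zn.T) * (1.0 / temperature)
    diag_mask = np.full((b2, b2), 0.0)
    np.fill_diagonal(diag_mask, -1e9)  # remove k = i from the denominator
    logits = logits + Tensor(diag_mask)
    pos_mask = np.zeros((b2, b2))
    pos_mask[np.arange(b2), (np.arange(b2) + b) % b2] = 1.0
    pos = (logits * Tensor(pos_mask)).sum(axis=1)
    rowmax = Tensor(logits.data.max(axis=1, keepdims=True))  # detached shift
    lse = ((logits - rowmax).exp().sum(axis=1)).log() + rowmax.reshape(b2)
    return (lse - pos).mean()


def _encode_batch(enc: nn.Module, batch: np.ndarray) -> Tensor:
    batch = apply_input_standardizer(enc, batch)
    if isinstance(enc, MLPEncoder):
        return enc(Tensor(batch))
    return enc(Tensor(reshape_input(batch)))


@dataclass
class PretrainResult:
    encoder: nn.Module
    encoder_config: EncoderConfig
    loss_history: np.ndarray  # per-epoch mean NT-Xent


def pretrain(
    matrix: FeatureMatrix,
    encoder_config: EncoderConfig = EncoderConfig(),
    projector_config: ProjectorConfig = ProjectorConfig(),
    ntxent_config: NTXentConfig = NTXentConfig(),
    config: PretrainConfig = PretrainConfig(),
    augment_config: AugmentConfig = AugmentConfig(),
) -> PretrainResult:
    """Contrastive pretraining over the (unlabeled) feature matrix.

    Per epoch the rows are reshuffled; each minibatch is augmented into a
    view pair, encoded, projected, and scored with NT-Xent; encoder and
    projector are updated jointly by AdamW under a cosine schedule.  The
    final incomplete minibatch is dropped (NT-Xent degenerates at b = 1).
    Returns the trained encoder and per-epoch mean loss; the projector is
    discarded.  Deterministic given the config seed.
    """
    m = len(matrix)
    if config.batch_size > m:
        raise ValueError(f"batch_size {config.batch_size} exceeds dataset size {m}")
    init_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0)))
    enc = build_encoder(encoder_config, init_rng)
    # the input standardizer is part of the pretrained artifact: fitted on the
    # pretraining matrix, applied after augmentation, frozen into checkpoints
    set_input_standardizer(enc, matrix.values)
    proj = Projector(encoder_config.output_dim, projector_config, init_rng)
    opt = AdamW(
        enc.parameters() + proj.parameters(),
        lr=config.learning_rate,
        weight_decay=config.weight_decay,
    )
    lr_at = cosine_schedule(config.learning_rate, config.epochs)
    steps = m // config.batch_size
    history = np.empty(config.epochs)
    for epoch in range(config.epochs):
        opt.lr = lr_at(epoch)
        order = np.random.default_rng(
            np.random.SeedSequence((config.seed, 1, epoch))
        ).permutation(m)
        epoch_losses = np.empty(steps)
        for step in range(steps):
            rows = order[step * config.batch_size : (step + 1) * config.batch_size]
            batch = matrix.values[rows]
            aug_rng = np.random.default_rng(
                np.random.SeedSequence((config.seed, 2, epoch, step))
            )
            v1, v2 = augment_batch(batch, augment_config, aug_rng)
            p1 = proj(_encode_batch(enc, v1))
            p2 = proj(_encode_batch(enc, v2))
            loss = _nt_xent_tensor(p1, p2, ntxent_config.temperature)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite NT-Xent loss at epoch {epoch}, step {step}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses[step] = loss.data
        history[epoch] = epoch_losses.mean()
        logger.debug("pretrain epoch %d: mean loss %.4f (lr %.5f)", epoch, history[epoch], opt.lr)
    return PretrainResult(encoder=enc, encoder_config=encoder_config, loss_history=history)
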