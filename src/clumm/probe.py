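"""Downstream motion classification on frozen encoder representations.

A multinomial logistic-regression head is trained on top of the (frozen)
encoder output h: class scores phi_k(h) = w_k . h + b_k pass through a
softmax, and (W, b) minimize the mean negative log-likelihood

    J(W, b) = -(1/n) sum_i log P(y_i | h_i)

by full-batch Adam under a multistep learning-rate decay.  Evaluation
follows the frozen-transfer protocol: stratified 5-fold cross-validation
with accuracy and macro-averaged precision / recall / F1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold

from . import nn
from ._autograd import Tensor
from .encoder import EncoderConfig, build_encoder, encode
from .landmarks import FeatureMatrix
from .optim import Adam, multistep_schedule

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeConfig",
    "ProbeWeights",
    "ClassificationMetrics",
    "softmax_probabilities",
    "nll_loss",
    "nll_gradients",
    "train_probe",
    "cross_validate",
    "evaluate",
    "baseline_transfer",
]


@dataclass(frozen=True)
class ProbeConfig:
    epochs: int = 100
    learning_rate: float = 0.01
    milestones: tuple[int, ...] = (50, 75)
    gamma: float = 0.1
    folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass
class ProbeWeights:
    """Linear head: W is (K, d) of per-class weight rows, biases length K."""

    W: np.ndarray
    biases: np.ndarray
    classes: np.ndarray  # label values, index k <-> class k

    def scores(self, features: np.ndarray) -> np.ndarray:
        return np.atleast_2d(features) @ self.W.T + self.biases


@dataclass
class ClassificationMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray
    classes: np.ndarray
    per_class: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "classes": [str(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class,
        }


def softmax_probabilities(scores: np.ndarray) -> np.ndarray:
    """Row-wise softmax with log-sum-exp stabilization."""
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    shifted = scores - scores.max(axis=1, keepdims=True)
    expd = np.exp(shifted)
    return expd / expd.sum(axis=1, keepdims=True)


def nll_loss(features: np.ndarray, y_idx: np.ndarray, weights: ProbeWeights) -> float:
    """Mean negative log-probability of the true classes."""
    scores = weights.scores(features)
    shifted = scores - scores.max(axis=1, keepdims=True)
    log_probs = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    return float(-log_probs[np.arange(len(y_idx)), y_idx].mean())


def nll_gradients(
    features: np.ndarray, y_idx: np.ndarray, weights: ProbeWeights
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradient of J w.r.t. (W, biases): mean of (p - onehot) x h."""
    X = np.atleast_2d(features)
    n = len(X)
    probs = softmax_probabilities(weights.scores(X))
    probs[np.arange(n), y_idx] -= 1.0
    return probs.T @ X / n, probs.mean(axis=0)


def _fit_softmax(
    X: np.ndarray, y_idx: np.ndarray, classes: np.ndarray, config: ProbeConfig
) -> tuple[ProbeWeights, np.ndarray]:
    k, d = len(classes), X.shape[1]
    head = ProbeWeights(W=np.zeros((k, d)), biases=np.zeros(k), classes=classes)
    # Adam state lives on Tensor views of W and b
    params = [Tensor(head.W, requires_grad=True), Tensor(head.biases, requires_grad=True)]
    opt = Adam(params, lr=config.learning_rate)
    lr_at = multistep_schedule(config.learning_rate, config.milestones, config.gamma)
    history = np.empty(config.epochs)
    for epoch in range(config.epochs):
        opt.lr = lr_at(epoch)
        head.W, head.biases = params[0].data, params[1].data
        gw, gb = nll_gradients(X, y_idx, head)
        params[0].grad, params[1].grad = gw, gb
        opt.step()
        head.W, head.biases = params[0].data, params[1].data
        history[epoch] = nll_loss(X, y_idx, head)
    head.W, head.biases = params[0].data, params[1].data
    return head, history


def _class_index(labels: np.ndarray, classes: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    if classes is None:
        classes = np.unique(labels)
    lookup = {c: i for i, c in enumerate(classes)}
    try:
        y_idx = np.array([lookup[l] for l in labels])
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]!r} outside the known classes {list(classes)}")
    return y_idx, np.asarray(classes)


def train_probe(
    encoder: nn.Module, matrix: FeatureMatrix, config: ProbeConfig = ProbeConfig()
) -> tuple[ProbeWeights, np.ndarray]:
    """Fit the linear head on frozen-encoder features of a labeled matrix.

    Only (W, b) are updated; the encoder is read, never written.  Returns
    the head and the per-epoch NLL history.
    """
    if matrix.labels is None:
        raise ValueError("labeled matrix required to train the probe")
    y_idx, classes = _class_index(matrix.labels)
    if len(classes) < 2:
        raise ValueError("at least two classes required")
    features = encode(encoder, matrix.values)
    return _fit_softmax(features, y_idx, classes, config)


def evaluate(weights: ProbeWeights, encoder: nn.Module, matrix: FeatureMatrix) -> ClassificationMetrics:
    """Accuracy, macro precision/recall/F1 and the confusion matrix."""
    if matrix.labels is None:
        raise ValueError("labeled matrix required for evaluation")
    y_idx, _ = _class_index(matrix.labels, weights.classes)
    features = encode(encoder, matrix.values)
    pred = weights.scores(features).argmax(axis=1)
    return _metrics_from_predictions(y_idx, pred, weights.classes)


def _metrics_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray
) -> ClassificationMetrics:
    label_ids = np.arange(len(classes))
    conf = _sk_confusion(y_true, y_pred, labels=label_ids)
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=label_ids, average=None, zero_division=0
    )
    per_class = {
        str(classes[i]): {
            "precision": float(prec[i]),
            "recall": float(rec[i]),
            "f1": float(f1[i]),
            "support": int(support[i]),
        }
        for i in label_ids
    }
    return ClassificationMetrics(
        accuracy=float((y_true == y_pred).mean()),
        precision=float(prec.mean()),
        recall=float(rec.mean()),
        f1=float(f1.mean()),
        confusion=conf,
        classes=classes,
        per_class=per_class,
    )


def cross_validate(
    encoder: nn.Module, matrix: FeatureMatrix, config: ProbeConfig = ProbeConfig()
) -> tuple[list[ClassificationMetrics], ClassificationMetrics]:
    """Stratified k-fold frozen-transfer evaluation.

    Folds partition the rows; metrics come from held-out predictions only.
    The mean report averages scalar metrics and sums fold confusion counts.
    """
    if matrix.labels is None:
        raise ValueError("labeled matrix required for cross-validation")
    y_idx, classes = _class_index(matrix.labels)
    counts = np.bincount(y_idx, minlength=len(classes))
    bad = [str(classes[i]) for i in np.where(counts < config.folds)[0]]
    if bad:
        raise ValueError(
            f"classes {bad} have fewer than {config.folds} samples; stratified "
            f"{config.folds}-fold CV is infeasible"
        )
    features = encode(encoder, matrix.values)
    splitter = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    fold_metrics: list[ClassificationMetrics] = []
    for train_rows, test_rows in splitter.split(features, y_idx):
        head, _ = _fit_softmax(features[train_rows], y_idx[train_rows], classes, config)
        pred = head.scores(features[test_rows]).argmax(axis=1)
        fold_metrics.append(_metrics_from_predictions(y_idx[test_rows], pred, classes))
    mean = ClassificationMetrics(
        accuracy=float(np.mean([f.accuracy for f in fold_metrics])),
        precision=float(np.mean([f.precision for f in fold_metrics])),
        recall=float(np.mean([f.recall for f in fold_metrics])),
        f1=float(np.mean([f.f1 for f in fold_metrics])),
        confusion=np.sum([f.confusion for f in fold_metrics], axis=0),
        classes=classes,
    )
    return fold_metrics, mean


def baseline_transfer(
    matrix: FeatureMatrix,
    encoder_config: EncoderConfig = EncoderConfig(),
    config: ProbeConfig = ProbeConfig(),
) -> tuple[list[ClassificationMetrics], ClassificationMetrics]:
    """Frozen-transfer baseline: same probe protocol on an untrained encoder.

    No pretrained weights ship with the package, so the baseline encoder is
    randomly initialized (seeded from the probe config) and frozen; this is
    the comparison row for contrastively pretrained encoders.
    """
    if encoder_config.pretrained_init:
        logger.warning("pretrained weights unavailable; falling back to random init")
        encoder_config = EncoderConfig(
            kind=encoder_config.kind,
            input_layout=encoder_config.input_layout,
            pretrained_init=False,
            repr_dim=encoder_config.repr_dim,
            mlp_hidden=encoder_config.mlp_hidden,
        )
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 3)))
    enc = build_encoder(encoder_config, rng)
    return cross_validate(enc, matrix, config)
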