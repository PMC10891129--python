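"""Transfer-learning protocol on the synthetic network-image corpus.

Three training regimes are compared on the binary (healthy vs T2D)
corpus, all built on one small convolutional network:

* ``TFE`` — feature extraction: the convolutional base keeps the
  weights learned on a multi-class source task; only a fresh
  densely-connected head is trained.
* ``TFT`` — fine-tuning: the bottom convolutional blocks stay frozen
  at source-task weights while the top block(s) and the fresh head are
  trained.
* ``SCRATCH`` — everything is freshly initialised and trained.

Predictions threshold the softmax healthy-class score at 0.5 (strictly
greater maps to "healthy", otherwise "T2D"); performance is summarised
through confusion matrices, BAC/ACC/PRE/REC/F1 and five-fold
cross-validation with a combined confusion matrix.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import nn
from .metrics import ConfusionMatrix, MetricsReport, compute_metrics, confusion_matrix
from .synthetic_data import BINARY_CLASS_NAMES, NetworkImageCorpus

__all__ = [
    "LayeredModelSpec",
    "TrainingConfig",
    "TransferConfig",
    "FoldAssignment",
    "CVReport",
    "SmallConvNet",
    "build_model",
    "pretrain_source",
    "adapt_classifier_head",
    "apply_transfer_mode",
    "train_classifier",
    "predict_proba",
    "predict_label",
    "fold_assignment",
    "five_fold_cv",
    "holdout_bac",
    "small_cnn_training",
    "source_training",
]

Mode = Literal["TFE", "TFT", "SCRATCH"]

HEALTHY_INDEX = 1  # class order: (T2D, healthy)


@dataclass(frozen=True)
class LayeredModelSpec:
    """Architecture of the small CNN: conv blocks then a dense head.

    Each conv block is (filters, kernel) followed by ReLU and 2×2 max
    pooling; after the blocks a global average pool feeds the head of
    hidden dense widths, with dropout on the last fully-connected layer
    before the softmax output.
    """

    conv_blocks: tuple[tuple[int, int], ...] = ((8, 3), (16, 3), (32, 3))
    head: tuple[int, ...] = (32,)
    dropout_rate: float = 0.5
    n_classes: int = 2
    weight_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_blocks) < 1 or len(self.head) < 1:
            raise ValueError("need at least one conv block and one head layer")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


@dataclass(frozen=True)
class TrainingConfig:
    """Training hyperparameters (loss is categorical cross-entropy)."""

    learning_rate: float = 1e-5
    epochs: int = 10
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs < 0 or self.batch_size < 1:
            raise ValueError("learning_rate, epochs and batch_size must be positive")


def small_cnn_training(seed: int = 0, epochs: int = 10, learning_rate: float = 1e-3) -> TrainingConfig:
    """Training defaults sized for the small CNN.

    The protocol's reference learning rate of 1e-5 targets very large
    pretrained backbones; the compact NumPy network trains at 1e-3 in
    the same 10-epoch / batch-32 budget.
    """
    return TrainingConfig(learning_rate=learning_rate, epochs=epochs, batch_size=32, seed=seed)


def source_training(seed: int = 0, epochs: int = 40, learning_rate: float = 1e-3) -> TrainingConfig:
    """Source-task pretraining budget for the small CNN.

    Long enough that source-task accuracy plateaus well above chance,
    so the transferred convolutional base carries genuinely learned
    features — the point of a pretrained source model.
    """
    return TrainingConfig(learning_rate=learning_rate, epochs=epochs, batch_size=32, seed=seed)


@dataclass(frozen=True)
class TransferConfig:
    mode: Mode = "TFE"
    freeze_blocks: int = 2
    optimizer_id: Literal["SGD", "RMSPROP", "ADAM"] = "ADAM"
    training: TrainingConfig = field(default_factory=TrainingConfig)


class SmallConvNet:
    """The CNN instance: a list of feature layers plus a head."""

    def __init__(self, spec: LayeredModelSpec, input_channels: int = 3):
        self.spec = spec
        self.input_channels = input_channels
        rng = np.random.default_rng(spec.weight_seed)
        self.feature_layers: list[nn.Layer] = []
        self.block_slices: list[slice] = []
        c_in = input_channels
        for filters, kernel in spec.conv_blocks:
            start = len(self.feature_layers)
            self.feature_layers.append(nn.Conv2D(c_in, filters, kernel, rng))
            self.feature_layers.append(nn.ReLU())
            self.feature_layers.append(nn.MaxPool2())
            self.block_slices.append(slice(start, len(self.feature_layers)))
            c_in = filters
        self.feature_layers.append(nn.GlobalAvgPool())
        self.n_features = c_in
        self.head_layers: list[nn.Layer] = self._make_head(rng)

    def _make_head(self, rng: np.random.Generator) -> list[nn.Layer]:
        layers: list[nn.Layer] = []
        d_in = self.n_features
        for width in self.spec.head:
            layers.append(nn.Dense(d_in, width, rng))
            layers.append(nn.ReLU())
            d_in = width
        layers.append(nn.Dropout(self.spec.dropout_rate))
        layers.append(nn.Dense(d_in, self.spec.n_classes, rng))
        return layers

    @property
    def layers(self) -> list[nn.Layer]:
        return self.feature_layers + self.head_layers

    @property
    def n_blocks(self) -> int:
        return len(self.block_slices)

    def block_layers(self, b: int) -> list[nn.Layer]:
        return self.feature_layers[self.block_slices[b]]

    def conv_weights(self) -> list[np.ndarray]:
        """Copies of every conv-base parameter tensor, in order."""
        return [
            layer.params[name].copy()
            for layer in self.feature_layers
            for name in sorted(layer.params)
        ]

    def all_weights(self) -> list[np.ndarray]:
        return [
            layer.params[name].copy() for layer in self.layers for name in sorted(layer.params)
        ]

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        return nn.forward_layers(self.layers, x, train=train, rng=rng)

    def clone(self) -> "SmallConvNet":
        return copy.deepcopy(self)


def build_model(spec: LayeredModelSpec, input_channels: int = 3) -> SmallConvNet:
    return SmallConvNet(spec, input_channels=input_channels)


# ---------------------------------------------------------------------------
# Corpus helpers
# ---------------------------------------------------------------------------

def _to_input(images: np.ndarray) -> np.ndarray:
    """Network input: ink density (1 − intensity) in NCHW layout.

    The drawings are dark strokes on a white canvas; inverting makes the
    background zero and the strokes positive, so conv activations are
    sparse and well-scaled for training.
    """
    return np.ascontiguousarray((1.0 - images).transpose(0, 3, 1, 2), dtype=np.float32)


def _corpus_arrays(corpus: NetworkImageCorpus) -> tuple[np.ndarray, np.ndarray]:
    x = _to_input(corpus.images)
    idx = corpus.label_indices
    onehot = np.zeros((len(idx), len(corpus.class_names)), dtype=np.float32)
    onehot[np.arange(len(idx)), idx] = 1.0
    return x, onehot


# ---------------------------------------------------------------------------
# Protocol operations
# ---------------------------------------------------------------------------

def pretrain_source(
    spec: LayeredModelSpec, corpus: NetworkImageCorpus, training: TrainingConfig
) -> SmallConvNet:
    """Train the full network on the multi-class source-task corpus."""
    if spec.n_classes != len(corpus.class_names):
        raise ValueError(
            f"spec expects {spec.n_classes} classes but the corpus has {len(corpus.class_names)}"
        )
    model = build_model(spec)
    x, onehot = _corpus_arrays(corpus)
    nn.train_layers(
        model.layers,
        x,
        onehot,
        optimizer="ADAM",
        learning_rate=training.learning_rate,
        epochs=training.epochs,
        batch_size=training.batch_size,
        seed=training.seed,
    )
    return model


def adapt_classifier_head(
    model: SmallConvNet, n_classes: int, head_seed: int | None = None
) -> SmallConvNet:
    """Replace the dense head with a fresh one of width ``n_classes``.

    Conv-base weights are left untouched (bit-identical). The new head
    is initialised from ``head_seed`` (derived from the model's weight
    seed when not given).
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if head_seed is None:
        head_seed = (model.spec.weight_seed + 1_000_003) % 2**31
    model.spec = replace(model.spec, n_classes=n_classes)
    model.head_layers = model._make_head(np.random.default_rng(head_seed))
    return model


def apply_transfer_mode(model: SmallConvNet, config: TransferConfig) -> SmallConvNet:
    """Set per-layer trainability according to the transfer mode.

    TFE freezes every conv block; TFT freezes the bottom
    ``freeze_blocks`` blocks (1 <= freeze_blocks < total); SCRATCH
    freshly reinitialises all weights and freezes nothing. The head is
    always trainable.
    """
    nb = model.n_blocks
    if config.mode == "TFE":
        frozen = set(range(nb))
    elif config.mode == "TFT":
        if not 1 <= config.freeze_blocks < nb:
            raise ValueError(
                f"TFT needs 1 <= freeze_blocks < {nb}; freezing all blocks would be TFE"
            )
        frozen = set(range(config.freeze_blocks))
    elif config.mode == "SCRATCH":
        fresh = build_model(
            replace(model.spec, weight_seed=(model.spec.weight_seed + config.training.seed + 7) % 2**31),
            input_channels=model.input_channels,
        )
        model.feature_layers = fresh.feature_layers
        model.head_layers = fresh.head_layers
        model.block_slices = fresh.block_slices
        frozen = set()
    else:
        raise ValueError(f"unknown transfer mode {config.mode!r}")

    for b in range(nb):
        for layer in model.block_layers(b):
            layer.trainable = b not in frozen
    for layer in model.head_layers:
        layer.trainable = True
    return model


def train_classifier(
    model: SmallConvNet, corpus: NetworkImageCorpus, config: TransferConfig
) -> SmallConvNet:
    """Train the unfrozen parameters on a binary corpus.

    When every conv block is frozen (TFE), the convolutional features
    are computed once and only the head is trained on them — the same
    computation, minus redundant frozen-base passes.
    """
    if len(corpus) == 0:
        raise ValueError("cannot train on an empty corpus")
    x, onehot = _corpus_arrays(corpus)
    tr = config.training
    if tr.epochs == 0:
        return model
    all_frozen = all(
        not layer.trainable for b in range(model.n_blocks) for layer in model.block_layers(b)
    )
    if all_frozen:
        feats = _forward_features(model, x)
        nn.train_layers(
            model.head_layers,
            feats,
            onehot,
            optimizer=config.optimizer_id,
            learning_rate=tr.learning_rate,
            epochs=tr.epochs,
            batch_size=tr.batch_size,
            seed=tr.seed,
        )
    else:
        nn.train_layers(
            model.layers,
            x,
            onehot,
            optimizer=config.optimizer_id,
            learning_rate=tr.learning_rate,
            epochs=tr.epochs,
            batch_size=tr.batch_size,
            seed=tr.seed,
        )
    return model


def _forward_features(model: SmallConvNet, x: np.ndarray, batch: int = 64) -> np.ndarray:
    outs = [
        nn.forward_layers(model.feature_layers, x[i : i + batch], train=False)
        for i in range(0, len(x), batch)
    ]
    return np.concatenate(outs, axis=0)


def predict_proba(model: SmallConvNet, images: np.ndarray, batch: int = 64) -> np.ndarray:
    """Softmax class probabilities for (N, H, W, 3) images in [0, 1]."""
    x = _to_input(images)
    outs = [
        nn.softmax(nn.forward_layers(model.layers, x[i : i + batch], train=False))
        for i in range(0, len(x), batch)
    ]
    return np.concatenate(outs, axis=0)


def predict_label(healthy_score: float) -> str:
    """Map a healthy-class score to a label: > 0.5 is healthy, else T2D."""
    if not 0.0 <= healthy_score <= 1.0:
        raise ValueError("healthy_score must lie in [0, 1]")
    return BINARY_CLASS_NAMES[1] if healthy_score > 0.5 else BINARY_CLASS_NAMES[0]


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldAssignment:
    """fold id in {0..n_folds-1} for each item index."""

    fold_of: np.ndarray
    n_folds: int

    def fold_indices(self, f: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == f)

    def sizes(self) -> list[int]:
        return [int((self.fold_of == f).sum()) for f in range(self.n_folds)]


def fold_assignment(
    n_items: int,
    n_folds: int = 5,
    seed: int = 0,
    labels: Sequence[str] | None = None,
) -> FoldAssignment:
    """Randomly partition items into folds whose sizes differ by <= 1.

    The default is a plain uniform permutation chunked into folds; pass
    ``labels`` for the optional stratified variant, which distributes
    each class round-robin over the folds after shuffling.
    """
    if n_items < n_folds:
        raise ValueError(f"need at least {n_folds} items for {n_folds} folds")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n_items, dtype=np.int64)
    if labels is None:
        perm = rng.permutation(n_items)
        for f, chunk in enumerate(np.array_split(perm, n_folds)):
            fold_of[chunk] = f
    else:
        labels = np.asarray(labels)
        offset = 0
        for cls in pd.unique(labels):
            idx = np.flatnonzero(labels == cls)
            idx = rng.permutation(idx)
            for j, item in enumerate(idx):
                fold_of[item] = (j + offset) % n_folds
            offset += len(idx)
    return FoldAssignment(fold_of=fold_of, n_folds=n_folds)


def holdout_bac(
    corpus: NetworkImageCorpus,
    spec: LayeredModelSpec,
    config: TransferConfig,
    split_seed: int = 0,
    source_model: SmallConvNet | None = None,
    test_fold: int = 0,
    n_folds: int = 5,
) -> float:
    """Balanced accuracy on one held-out fold for one configuration.

    A lighter companion to :func:`five_fold_cv`: the corpus is split as
    for cross-validation but only ``test_fold`` is evaluated — the unit
    of the seed-averaged transfer-benefit comparison.
    """
    if config.mode in ("TFE", "TFT") and source_model is None:
        raise ValueError(f"{config.mode} evaluation needs a pretrained source_model")
    assignment = fold_assignment(len(corpus), n_folds, seed=split_seed)
    test_idx = assignment.fold_indices(test_fold % n_folds)
    train_idx = np.flatnonzero(assignment.fold_of != test_fold % n_folds)
    train_corpus = NetworkImageCorpus(
        images=corpus.images[train_idx],
        labels=[corpus.labels[i] for i in train_idx],
        class_names=corpus.class_names,
        class_params=corpus.class_params,
        image_size=corpus.image_size,
        seed=corpus.seed,
    )
    if config.mode == "SCRATCH":
        model = build_model(replace(spec, n_classes=2))
    else:
        model = source_model.clone()
        adapt_classifier_head(model, 2, head_seed=(split_seed * 131 + test_fold) % 2**31)
    model = apply_transfer_mode(model, config)
    model = train_classifier(model, train_corpus, config)
    proba = predict_proba(model, corpus.images[test_idx])
    preds = [predict_label(float(s)) for s in proba[:, HEALTHY_INDEX]]
    cm = confusion_matrix([corpus.labels[i] for i in test_idx], preds)
    return compute_metrics(cm).bac


@dataclass(frozen=True)
class CVReport:
    per_fold: tuple[tuple[ConfusionMatrix, MetricsReport], ...]
    combined_confusion: ConfusionMatrix
    averages: dict[str, float]
    mode: str
    optimizer_id: str

    def metrics_frame(self) -> pd.DataFrame:
        rows = [
            {"fold": f, **mr.as_dict(), "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn}
            for f, (cm, mr) in enumerate(self.per_fold)
        ]
        return pd.DataFrame(rows)


def five_fold_cv(
    corpus: NetworkImageCorpus,
    spec: LayeredModelSpec,
    config: TransferConfig,
    split_seed: int = 0,
    source_model: SmallConvNet | None = None,
    n_folds: int = 5,
    stratified: bool = False,
) -> CVReport:
    """Five-fold cross-validation of one (mode, optimizer) configuration.

    Each fold serves once as the test set while the remaining folds
    train the model; per-fold metrics are averaged arithmetically and
    the per-fold confusion matrices sum to the combined matrix, so each
    image is tested exactly once.

    TFE/TFT need a ``source_model`` pretrained on the source task; its
    conv base is cloned per fold, the head re-adapted and the freeze
    mask applied. SCRATCH builds a fresh model per fold.
    """
    if len(corpus) < n_folds:
        raise ValueError(f"corpus must hold at least {n_folds} items")
    if config.mode in ("TFE", "TFT") and source_model is None:
        raise ValueError(f"{config.mode} cross-validation needs a pretrained source_model")
    assignment = fold_assignment(
        len(corpus), n_folds, seed=split_seed, labels=corpus.labels if stratified else None
    )
    labels = np.asarray(corpus.labels)
    per_fold: list[tuple[ConfusionMatrix, MetricsReport]] = []
    for f in range(n_folds):
        test_idx = assignment.fold_indices(f)
        train_idx = np.flatnonzero(assignment.fold_of != f)
        train_corpus = NetworkImageCorpus(
            images=corpus.images[train_idx],
            labels=[corpus.labels[i] for i in train_idx],
            class_names=corpus.class_names,
            class_params=corpus.class_params,
            image_size=corpus.image_size,
            seed=corpus.seed,
        )
        fold_training = replace(config.training, seed=config.training.seed + f)
        fold_config = replace(config, training=fold_training)
        if config.mode == "SCRATCH":
            model = build_model(replace(spec, n_classes=2))
        else:
            model = source_model.clone()
            adapt_classifier_head(model, 2, head_seed=(split_seed * 31 + f) % 2**31)
        model = apply_transfer_mode(model, fold_config)
        model = train_classifier(model, train_corpus, fold_config)
        proba = predict_proba(model, corpus.images[test_idx])
        preds = [predict_label(float(s)) for s in proba[:, HEALTHY_INDEX]]
        cm = confusion_matrix(list(labels[test_idx]), preds)
        per_fold.append((cm, compute_metrics(cm)))
    combined = per_fold[0][0]
    for cm, _ in per_fold[1:]:
        combined = combined + cm
    averages = {
        name: float(np.mean([mr.as_dict()[name] for _, mr in per_fold]))
        for name in ("BAC", "ACC", "PRE", "REC", "F1")
    }
    return CVReport(
        per_fold=tuple(per_fold),
        combined_confusion=combined,
        averages=averages,
        mode=config.mode,
        optimizer_id=config.optimizer_id,
    )
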