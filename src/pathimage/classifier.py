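"""CNN classification of pathway images and the evaluation-metric suite.

The network is a stack of convolution blocks (conv -> batch-norm -> ReLU ->
max-pool), a flatten, one dense block (dense -> batch-norm -> ReLU ->
dropout) and a softmax output over the two survival classes.  The default
geometry uses height-1 kernels and width-only pooling: pathway rows are
independent signals in an arbitrary order, so convolving or pooling across
rows mixes unrelated pathways and buries single-pathway effects, while
row-preserving blocks keep each pathway's identity up to the dense layer.
Training uses Adam with a held-out validation split; the weights with the
best validation accuracy are retained.  Evaluation is stratified k-fold
cross-validation with accuracy, precision, recall, F1, ROC AUC and the
confusion matrix.

The positive class throughout is non-LTS (the shorter-surviving group).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from . import nn
from .data_io import LTS, NON_LTS, HarmonizedDataset, PathwayCollection
from .embedding import ImageStack, build_image_stack

logger = logging.getLogger(__name__)


@dataclass
class CnnConfig:
    n_conv_layers: int = 2
    filters: tuple[int, ...] = (8, 16)
    kernel_sizes: tuple[tuple[int, int], ...] = ((1, 3), (1, 3))
    pool_sizes: tuple[tuple[int, int], ...] = ((1, 2), (1, 1))
    dense_width: int = 32
    dropout_rate: float = 0.5
    learning_rate: float = 1e-3
    weight_decay: float = 1e-3  # decoupled L2 on weight matrices
    epochs: int = 60
    batch_size: int = 4  # small batches regularize strongly on ~10^2-sample cohorts
    validation_split: float = 0.2
    n_ensemble: int = 4  # independently seeded members; probabilities averaged
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "n_conv_layers": self.n_conv_layers,
            "filters": list(self.filters),
            "kernel_sizes": [list(k) for k in self.kernel_sizes],
            "pool_sizes": [list(p) for p in self.pool_sizes],
            "dense_width": self.dense_width,
            "dropout_rate": self.dropout_rate,
            "learning_rate": self.learning_rate,
            "weight_decay": self.weight_decay,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "validation_split": self.validation_split,
            "n_ensemble": self.n_ensemble,
            "seed": self.seed,
        }


@dataclass
class TrainedModel:
    networks: list[nn.Network]  # ensemble members; probabilities averaged
    config: CnnConfig
    input_shape: tuple[int, int]
    class_order: list[str]  # index -> class label; [LTS, non-LTS] by default
    history: dict[str, list[float]] = field(default_factory=dict)

    @property
    def network(self) -> nn.Network:
        return self.networks[0]

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Ensemble-mean class probabilities for (n, h, w) images."""
        x = np.asarray(images, dtype=float)[:, None, :, :]
        return np.mean([net.predict_proba(x) for net in self.networks], axis=0)

    def input_gradient(self, images: np.ndarray, target_class: int) -> np.ndarray:
        """Gradient of the ensemble-mean target probability w.r.t. inputs."""
        x = np.asarray(images, dtype=float)[:, None, :, :]
        return np.mean([net.input_gradient(x, target_class)[:, 0]
                        for net in self.networks], axis=0)


@dataclass
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass
class MetricsReport:
    accuracy: float
    precision: float  # NaN when TP+FP = 0 (undefined, reported as NA)
    recall: float
    f1: float
    auc_roc: float  # NaN when only one class present
    confusion: ConfusionMatrix

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc_roc": self.auc_roc,
            "tp": self.confusion.tp,
            "tn": self.confusion.tn,
            "fp": self.confusion.fp,
            "fn": self.confusion.fn,
        }


def rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC as the Mann-Whitney rank statistic (ties get half credit)."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(
    y_true: np.ndarray,
    y_prob: np.ndarray,
    positive_index: int = 1,
    threshold: float = 0.5,
) -> MetricsReport:
    """All six metrics from class-probability outputs.

    ``y_true`` holds class indices; ``y_prob`` rows are probability vectors.
    Predictions call the positive class when its probability exceeds
    ``threshold``.  Undefined precision/F1 (no positive calls) and AUC on a
    single-class truth vector are reported as NaN.
    """
    y_true = np.asarray(y_true)
    y_prob = np.asarray(y_prob, dtype=float)
    if not np.allclose(y_prob.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    pos_scores = y_prob[:, positive_index]
    y_pred_pos = pos_scores > threshold
    y_is_pos = y_true == positive_index
    tp = int(np.sum(y_pred_pos & y_is_pos))
    tn = int(np.sum(~y_pred_pos & ~y_is_pos))
    fp = int(np.sum(y_pred_pos & ~y_is_pos))
    fn = int(np.sum(~y_pred_pos & y_is_pos))
    cm = ConfusionMatrix(tp, tn, fp, fn)
    accuracy = (tp + tn) / cm.n
    precision = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    recall = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    if np.isnan(precision) or np.isnan(recall) or (precision + recall) == 0:
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    auc = rank_auc(y_is_pos.astype(int), pos_scores)
    if np.isnan(auc):
        logger.warning("AUC undefined: only one class present in y_true")
    return MetricsReport(accuracy, precision, recall, f1, auc, cm)


def _check_geometry(config: CnnConfig, input_shape: tuple[int, int]) -> None:
    h, w = input_shape
    for i, (ph, pw) in enumerate(config.pool_sizes[: config.n_conv_layers]):
        h, w = h // ph, w // pw
        if h < 1 or w < 1:
            raise ValueError(
                f"pool layer {i + 1} (size {ph}x{pw}) collapses the image to "
                f"{h}x{w}; reduce pooling for input {input_shape}"
            )


def build_cnn(config: CnnConfig, input_shape: tuple[int, int], n_classes: int = 2) -> nn.Network:
    """Assemble the untrained network for (h, w) single-channel images."""
    _check_geometry(config, input_shape)
    ss = np.random.SeedSequence(config.seed)
    init_rng, drop_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
    layers: list[nn.Layer] = []
    c_in = 1
    h, w = input_shape
    for i in range(config.n_conv_layers):
        kh, kw = config.kernel_sizes[i]
        f = config.filters[i]
        layers += [
            nn.Conv2D(c_in, f, kh, kw, init_rng),
            nn.BatchNorm(f, spatial=True),
            nn.ReLU(),
            nn.MaxPool(*config.pool_sizes[i]),
        ]
        ph, pw = config.pool_sizes[i]
        h, w, c_in = h // ph, w // pw, f
    layers += [
        nn.Flatten(),
        nn.Dense(h * w * c_in, config.dense_width, init_rng),
        nn.BatchNorm(config.dense_width, spatial=False),
        nn.ReLU(),
        nn.Dropout(config.dropout_rate, drop_rng),
        nn.Dense(config.dense_width, n_classes, init_rng),
    ]
    net = nn.Network(layers)
    n_params = sum(p.size for l in layers for _, _, p, _ in l.param_pairs())
    logger.info("built CNN with %d parameters for input %s", n_params, input_shape)
    return net


def _train_single(images: np.ndarray, y: np.ndarray, config: CnnConfig):
    """Train one network; returns (net, history). See ``train``."""
    n_classes = int(y.max()) + 1
    net = build_cnn(config, images.shape[1:], n_classes)
    ss = np.random.SeedSequence(config.seed + 1_000_003)
    split_rng, shuffle_rng = [np.random.default_rng(s) for s in ss.spawn(2)]

    # Stratified validation split.
    val_idx: list[int] = []
    for c in np.unique(y):
        members = np.flatnonzero(y == c)
        k = max(1, int(round(config.validation_split * members.size)))
        val_idx.extend(split_rng.permutation(members)[:k])
    val_mask = np.zeros(len(y), dtype=bool)
    val_mask[val_idx] = True
    x_tr, y_tr = images[~val_mask][:, None], y[~val_mask]
    x_val, y_val = images[val_mask][:, None], y[val_mask]

    opt = nn.Adam(net, lr=config.learning_rate, weight_decay=config.weight_decay)
    history: dict[str, list[float]] = {"loss": [], "val_accuracy": [], "val_auc": []}
    best_score, best_weights = (-1.0, -1.0), None
    n_tr = x_tr.shape[0]
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n_tr)
        losses = []
        for start in range(0, n_tr, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss = net.loss_and_grad(x_tr[idx], y_tr[idx], train=True)
            if not np.isfinite(loss):
                raise RuntimeError(f"NaN/inf loss at epoch {epoch}, batch {start // config.batch_size}")
            opt.step()
            losses.append(loss)
        val_prob = net.predict_proba(x_val)
        val_acc = float(np.mean(val_prob.argmax(axis=1) == y_val))
        # Selection by validation AUC (accuracy as tie-break): AUC has finer
        # granularity than accuracy on small validation splits and matches
        # the reported metric.  The stratified split guarantees both classes.
        val_auc = rank_auc((y_val == y_val.max()).astype(int), val_prob[:, -1])
        history["loss"].append(float(np.mean(losses)))
        history["val_accuracy"].append(val_acc)
        history["val_auc"].append(val_auc)
        score = (val_auc, val_acc)
        if score > best_score:
            best_score = score
            best_weights = net.get_weights()
    if best_weights is not None:
        net.set_weights(best_weights)
    return net, history


def train(
    images: np.ndarray,
    y: np.ndarray,
    config: CnnConfig,
    class_order: list[str] | None = None,
) -> TrainedModel:
    """Train the CNN on (n, h, w) images with integer class labels.

    ``n_ensemble`` networks are trained with member-specific seeds (distinct
    initializations, validation splits and batch orders) and predict by
    averaging probabilities — individual runs on small cohorts have high
    seed-to-seed variance that the ensemble mean removes.  Within each
    member a stratified ``validation_split`` fraction is held out; after
    each epoch validation accuracy is recorded and the best-validation
    weights are restored.  Aborts on NaN loss.  The reported history holds
    per-epoch means over members.
    """
    images = np.asarray(images, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if config.n_ensemble < 1:
        raise ValueError("n_ensemble must be >= 1")
    nets, histories = [], []
    for j in range(config.n_ensemble):
        member_cfg = config if j == 0 else CnnConfig(
            **{**config.to_dict(),
               "kernel_sizes": config.kernel_sizes,
               "pool_sizes": config.pool_sizes,
               "filters": config.filters,
               "seed": config.seed + 104_729 * j})
        net, hist = _train_single(images, y, member_cfg)
        nets.append(net)
        histories.append(hist)
    history = {
        key: list(np.mean([h[key] for h in histories], axis=0))
        for key in histories[0]
    }
    return TrainedModel(
        networks=nets,
        config=config,
        input_shape=images.shape[1:],
        class_order=class_order or [LTS, NON_LTS],
        history=history,
    )


@dataclass
class CrossValidationResult:
    fold_models: list[TrainedModel]
    fold_reports: list[MetricsReport]
    pooled: MetricsReport
    y_true: np.ndarray       # pooled over folds, original sample order
    y_prob: np.ndarray
    fold_of_sample: np.ndarray
    fold_stacks: list[ImageStack] = None


def labels_to_indices(dataset: HarmonizedDataset) -> tuple[np.ndarray, list[str]]:
    """Integer class vector over dataset.sample_ids; order [LTS, non-LTS]."""
    order = dataset.class_labels
    index = {c: i for i, c in enumerate(order)}
    y = np.array([index[dataset.class_of(s)] for s in dataset.sample_ids], dtype=int)
    return y, order


def cross_validate(
    dataset: HarmonizedDataset,
    pathways: PathwayCollection,
    cnn_config: CnnConfig,
    n_pcs: int = 2,
    k: int = 5,
    mode: str = "fold-safe",
    seed: int = 0,
    stack: ImageStack | None = None,
) -> CrossValidationResult:
    """Stratified k-fold CV of the full embed-and-classify pipeline.

    In ``fold-safe`` mode the PCA embedding bank is refitted on each fold's
    training samples only.  In ``paper-faithful`` mode one all-sample bank is
    reused across folds (pass ``stack`` to avoid refitting).  Reports are
    produced per fold and pooled (micro-averaged confusion, AUC over the
    pooled test probabilities).
    """
    y, class_order = labels_to_indices(dataset)
    counts = np.bincount(y)
    if counts.min() < k:
        raise ValueError(f"k={k} exceeds smallest class size {counts.min()}")
    if mode == "paper-faithful" and stack is None:
        stack, _ = build_image_stack(dataset, pathways, n_pcs, mode="paper-faithful")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    n = len(dataset.sample_ids)
    y_prob = np.zeros((n, len(class_order)))
    fold_of_sample = np.full(n, -1, dtype=int)
    fold_models: list[TrainedModel] = []
    fold_reports: list[MetricsReport] = []
    fold_stacks: list[ImageStack] = []
    for fold, (tr_idx, te_idx) in enumerate(skf.split(np.zeros(n), y)):
        if mode == "fold-safe":
            train_samples = [dataset.sample_ids[i] for i in tr_idx]
            fold_stack, _ = build_image_stack(
                dataset, pathways, n_pcs, mode="fold-safe", fold_train_samples=train_samples
            )
        else:
            fold_stack = stack
        fold_stacks.append(fold_stack)
        cfg = CnnConfig(**{**cnn_config.to_dict(),
                           "kernel_sizes": cnn_config.kernel_sizes,
                           "pool_sizes": cnn_config.pool_sizes,
                           "filters": cnn_config.filters,
                           "seed": cnn_config.seed + fold})
        model = train(fold_stack.tensor[tr_idx], y[tr_idx], cfg, class_order)
        prob = model.predict_proba(fold_stack.tensor[te_idx])
        y_prob[te_idx] = prob
        fold_of_sample[te_idx] = fold
        fold_models.append(model)
        fold_reports.append(compute_metrics(y[te_idx], prob))
        logger.info("fold %d: %s", fold, fold_reports[-1].to_dict())
    pooled = compute_metrics(y, y_prob)
    return CrossValidationResult(fold_models, fold_reports, pooled, y, y_prob,
                                 fold_of_sample, fold_stacks)
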