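"""Losses, schedules, the mixed image/embedding training loop, and protocols.

Training of the hybrid model uses AdamW with cosine-annealed learning rate,
weighted cross-entropy (class weights inversely proportional to training-fold
class counts) with label smoothing, and the augmentation stack from
:mod:`fusecyte.dataio`.  When a SMOTE-balanced embedding set is supplied, its
rows enter the network at the fusion point — after concatenation, before
projection — in batches interleaved with the real-image batches; they can
therefore only ever update head parameters, which is asserted as the
gradient-isolation property.

Validation and test metrics are computed exclusively on real images; a
leakage audit runs before training and the driver refuses to proceed if it
fails.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from fusecyte.balance import EmbeddingSet, LeakageError, leakage_guard
from fusecyte.constants import N_CLASSES
from fusecyte.dataio import (AugmentConfig, DatasetManifest, SplitPlan, load_image,
                             make_dual_views, mixup_cutmix)
from fusecyte.models import HybridModel

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig", "TrainHistory", "AdamW", "weighted_cross_entropy",
    "class_weights_from_counts", "cosine_lr", "train_model", "run_protocol",
]


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    Defaults follow the reference configuration: AdamW + cosine annealing,
    weighted cross-entropy with label smoothing 0.1, batch size 16, 80 epochs
    for the hybrid model.  ``augment=False`` disables the stochastic pipeline
    entirely (eval-mode views), which also lets the loop cache fusion-point
    embeddings of the frozen branches between epochs.
    """

    lr_head: float = 1e-3
    lr_backbone: float = 1e-5
    weight_decay: float = 0.05
    lr_min: float = 0.0
    epochs: int = 80
    batch_size: int = 16
    label_smoothing: float = 0.1
    class_weights: np.ndarray | None = None  # derived from train counts if None
    mixup_alpha: float = 0.2
    cutmix_alpha: float = 1.0
    apply_prob: float = 0.5
    stochastic_depth_rate: float = 0.1
    augment: bool = True
    aug: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 2 and self.apply_prob > 0 and self.augment:
            raise ValueError("batch_size must be >= 2 when MixUp/CutMix is enabled")
        if not 0.0 <= self.label_smoothing < 1.0:
            raise ValueError("label_smoothing must lie in [0, 1)")
        if self.class_weights is not None:
            w = np.asarray(self.class_weights, dtype=np.float64)
            if w.shape != (N_CLASSES,) or not np.all(np.isfinite(w)) or np.any(w <= 0):
                raise ValueError("class_weights must be a finite positive 3-vector")
            self.class_weights = w


@dataclass
class TrainHistory:
    """Per-epoch training records."""

    records: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def column(self, name: str) -> list:
        return [r[name] for r in self.records]

    def to_csv(self, path: str | Path) -> None:
        import csv
        with open(path, "w", newline="", encoding="utf-8") as fh:
            if not self.records:
                fh.write("epoch,train_loss,val_loss,val_accuracy,learning_rate\n")
                return
            writer = csv.DictWriter(fh, fieldnames=list(self.records[0]))
            writer.writeheader()
            writer.writerows(self.records)


def class_weights_from_counts(class_counts: Sequence[float] | dict) -> np.ndarray:
    """Inverse-frequency class weights ``w_c = N / (K * n_c)``.

    Normalized so that ``sum_c w_c * n_c = N``; invariant to scaling all
    counts by a common factor.
    """
    if isinstance(class_counts, dict):
        from fusecyte.constants import CLASSES
        counts = np.array([class_counts[c] for c in CLASSES], dtype=np.float64)
    else:
        counts = np.asarray(class_counts, dtype=np.float64)
    if np.any(counts <= 0):
        raise ValueError("class counts must be positive")
    n = counts.sum()
    return n / (counts.size * counts)


def weighted_cross_entropy(probs: np.ndarray, target: np.ndarray,
                           class_weights: np.ndarray | None = None,
                           label_smoothing: float = 0.0) -> float:
    """Weighted cross-entropy with label smoothing for (soft) targets.

    ``loss = -sum_c w_c * t~_c * ln p_c`` with smoothed target
    ``t~ = (1 - eps) * t + eps / K``.  Weights apply per component; for a
    hard one-hot target this equals weighting by the target's argmax class.
    Accepts single vectors or batches (mean over the batch).
    """
    p = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    t = np.atleast_2d(np.asarray(target, dtype=np.float64))
    if p.shape != t.shape:
        raise ValueError("probs and target must have matching shapes")
    w = np.ones(p.shape[1]) if class_weights is None else np.asarray(class_weights)
    t_sm = (1.0 - label_smoothing) * t + label_smoothing / p.shape[1]
    if np.any((p <= 0) & (t_sm > 0)):
        logger.warning("zero predicted probability at a supported class; clamping at 1e-12")
    p = np.clip(p, 1e-12, None)
    losses = -(w * t_sm * np.log(p)).sum(axis=1)
    return float(losses.mean())


def cosine_lr(t: float, T_max: int, lr_max: float, lr_min: float = 0.0) -> float:
    """Cosine annealing: ``lr(t) = lr_min + (lr_max - lr_min)(1 + cos(pi t / T_max)) / 2``."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if t > T_max:
        logger.warning("cosine_lr called with t=%s > T_max=%s; clamping to lr_min", t, T_max)
        return lr_min
    if T_max == 0:
        return lr_max
    return lr_min + 0.5 * (lr_max - lr_min) * (1.0 + math.cos(math.pi * t / T_max))


class AdamW(object):
    """AdamW over a dict of named parameter arrays (decoupled weight decay)."""

    def __init__(self, params: dict[str, np.ndarray], weight_decay: float = 0.05,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p -= lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p)


def _wce_dlogits(probs: np.ndarray, targets: np.ndarray, w: np.ndarray,
                 eps: float) -> np.ndarray:
    """d(mean weighted smoothed CE)/d logits for a softmax output."""
    t_sm = (1.0 - eps) * targets + eps / probs.shape[1]
    wt = w * t_sm
    return (probs * wt.sum(axis=1, keepdims=True) - wt) / probs.shape[0]


def _one_hot(labels: np.ndarray) -> np.ndarray:
    out = np.zeros((labels.size, N_CLASSES))
    out[np.arange(labels.size), labels] = 1.0
    return out


def train_model(manifest: DatasetManifest, split_plan: SplitPlan, model: HybridModel,
                config: TrainConfig,
                balanced_embeddings: EmbeddingSet | None = None,
                val_fold: int = 0):
    """Train the hybrid model's head on one split; return (checkpoint, history).

    Each epoch iterates real-image batches (augmented, optionally
    MixUp/CutMix-regularized) through both frozen branches and the trainable
    head; when ``balanced_embeddings`` is given, embedding batches are
    interleaved and injected at the fusion point, updating head parameters
    only.  Validation runs on real images under eval-mode preprocessing.  The
    checkpoint with the highest validation accuracy (ties: earliest epoch) is
    returned.
    """
    if split_plan.kind == "holdout":
        train_ids = split_plan.role_ids("train")
        val_ids = split_plan.role_ids("val")
    else:
        val_ids = split_plan.role_ids(val_fold)
        train_ids = sorted(set(split_plan.assignments) - set(val_ids))

    if balanced_embeddings is not None:
        if balanced_embeddings.source_split != "train":
            raise LeakageError("balanced embeddings must be training-tagged")
        real_ids = set(int(i) for i in balanced_embeddings.record_ids if i >= 0)
        if not real_ids <= set(train_ids):
            raise LeakageError("balanced embeddings contain non-training records")
        audit = leakage_guard(split_plan, [balanced_embeddings])
        if not audit.passed:
            raise LeakageError(f"leakage audit failed: {audit.to_dict()}")

    rng = np.random.default_rng(config.seed)
    labels = manifest.labels
    weights = config.class_weights
    if weights is None:
        counts = np.bincount(labels[train_ids], minlength=N_CLASSES)
        weights = class_weights_from_counts(np.maximum(counts, 1))

    history = TrainHistory()
    best = {"val_accuracy": -1.0, "epoch": -1, "head": model.head.copy()}
    if config.epochs == 0:
        return best, history

    images = {i: load_image(manifest.records[i].path) for i in train_ids + val_ids}
    eval_aug = config.aug

    def embed_eval(ids: list[int]) -> np.ndarray:
        chunks = []
        for start in range(0, len(ids), 64):
            sub = ids[start:start + 64]
            samples = [make_dual_views(images[i], aug=eval_aug) for i in sub]
            tv = np.stack([s.transformer_view for s in samples])
            cv = np.stack([s.cnn_view for s in samples])
            chunks.append(model.embed_views(tv, cv))
        return np.concatenate(chunks, axis=0)

    val_z = embed_eval(val_ids) if val_ids else np.zeros((0, model.fusion_input_dim))
    val_t = _one_hot(labels[val_ids]) if val_ids else np.zeros((0, N_CLASSES))
    cached_train_z = None if config.augment else embed_eval(train_ids)

    if model.head.input_mean is None:
        # freeze fusion-point normalization on training-fold statistics
        calib = cached_train_z if cached_train_z is not None else embed_eval(train_ids)
        model.head.calibrate(calib)

    optimizer = AdamW(model.head.as_dict(), weight_decay=config.weight_decay)
    synth_order = None
    if balanced_embeddings is not None:
        synth_order = np.arange(len(balanced_embeddings))

    for epoch in range(config.epochs):
        lr = cosine_lr(epoch, config.epochs, config.lr_head, config.lr_min)
        order = rng.permutation(len(train_ids))
        epoch_losses: list[float] = []

        def head_step(z: np.ndarray, t: np.ndarray) -> None:
            z_p, probs = model.head_forward(z)
            loss = weighted_cross_entropy(probs, t, weights, config.label_smoothing)
            if not math.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}: {loss}")
            dlogits = _wce_dlogits(probs, t, weights, config.label_smoothing)
            optimizer.step(model.head_backward(z, z_p, dlogits), lr)
            epoch_losses.append(loss)

        emb_cursor = 0
        if synth_order is not None:
            rng.shuffle(synth_order)
        for start in range(0, len(order), config.batch_size):
            batch_ids = [train_ids[i] for i in order[start:start + config.batch_size]]
            if cached_train_z is not None:
                pos = order[start:start + config.batch_size]
                z = cached_train_z[pos]
                t = _one_hot(labels[batch_ids])
            else:
                samples = [make_dual_views(images[i], train_mode=True, aug=config.aug,
                                           rng=rng, label=int(labels[i]))
                           for i in batch_ids]
                samples = mixup_cutmix(samples, config.mixup_alpha, config.cutmix_alpha,
                                       config.apply_prob, rng)
                tv = np.stack([s.transformer_view for s in samples])
                cv = np.stack([s.cnn_view for s in samples])
                z = model.embed_views(tv, cv, train_mode=True, rng=rng)
                t = np.stack([s.label for s in samples])
            head_step(z, t)

            if synth_order is not None and emb_cursor < len(synth_order):
                # interleave one fusion-point embedding batch per image batch
                pos = synth_order[emb_cursor:emb_cursor + config.batch_size]
                emb_cursor += config.batch_size
                head_step(balanced_embeddings.vectors[pos],
                          _one_hot(balanced_embeddings.labels[pos]))

        if len(val_ids):
            _, val_probs = model.head_forward(val_z)
            val_loss = weighted_cross_entropy(val_probs, val_t, weights,
                                              config.label_smoothing)
            val_acc = float((val_probs.argmax(axis=1) == labels[val_ids]).mean())
        else:
            val_loss, val_acc = float("nan"), float("nan")
        history.records.append({
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)) if epoch_losses else float("nan"),
            "val_loss": val_loss, "val_accuracy": val_acc, "learning_rate": lr,
        })
        if len(val_ids) and val_acc > best["val_accuracy"]:
            best = {"val_accuracy": val_acc, "epoch": epoch, "head": model.head.copy()}

    if not len(val_ids):
        best = {"val_accuracy": float("nan"), "epoch": config.epochs - 1,
                "head": model.head.copy()}
    return best, history


def evaluate_model(manifest: DatasetManifest, model: HybridModel, ids: Sequence[int],
                   aug: AugmentConfig | None = None):
    """Eval-mode metrics of the model on the given (real-image) records."""
    from fusecyte.evalreport import compute_metrics
    aug = aug or AugmentConfig()
    probs_chunks = []
    for start in range(0, len(ids), 64):
        sub = list(ids)[start:start + 64]
        tv, cv = [], []
        for i in sub:
            s = make_dual_views(load_image(manifest.records[i].path), aug=aug)
            tv.append(s.transformer_view)
            cv.append(s.cnn_view)
        probs_chunks.append(model.predict_proba(np.stack(tv), np.stack(cv)))
    probs = np.concatenate(probs_chunks, axis=0)
    return compute_metrics(manifest.labels[list(ids)], probs)


def run_protocol(manifest: DatasetManifest, config: TrainConfig,
                 model_factory: Callable[[int], HybridModel], n_seeds: int = 3,
                 fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)):
    """Repeat the holdout experiment over seeds and aggregate mean metrics.

    Each seed gets its own stratified 70/15/15 split, model initialization
    and training run; the report carries per-seed metrics plus the arithmetic
    mean of the scalar summaries.  A failed seed flags the report incomplete
    rather than aborting the protocol.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    per_seed = []
    incomplete = False
    for seed in range(n_seeds):
        try:
            plan = stratified_holdout_for(manifest, fractions, seed)
            model = model_factory(seed)
            cfg = replace(config, seed=seed)
            checkpoint, history = train_model(manifest, plan, model, cfg)
            model.head = checkpoint["head"]
            report = evaluate_model(manifest, model, plan.role_ids("test"), cfg.aug)
            per_seed.append({
                "seed": seed,
                "val_accuracy": checkpoint["val_accuracy"] * 100.0,
                "test_accuracy": report.accuracy,
                "macro_f1": report.macro_f1,
                "report": report,
            })
        except Exception:  # pragma: no cover - defensive protocol behavior
            logger.exception("seed %d failed", seed)
            incomplete = True
    mean = {}
    if per_seed:
        for key in ("val_accuracy", "test_accuracy", "macro_f1"):
            mean[key] = float(np.mean([r[key] for r in per_seed]))
    return {"per_seed": per_seed, "mean": mean, "incomplete": incomplete}


def stratified_holdout_for(manifest, fractions, seed):
    from fusecyte.dataio import stratified_holdout
    return stratified_holdout(manifest, fractions, seed)
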