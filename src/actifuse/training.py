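"""Training and evaluation: focal loss, subject-level stratified splitting,
k-fold cross-validation, the AdamW training loop and the evaluation harness.

Splitting is always at the participant level — no subject contributes
sequences to more than one of train/validation/test, and every cross-
validation fold is a disjoint subject set. Class imbalance is handled by
focal loss with inverse-frequency class weights.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, no_grad
from .dataset import SequenceDataset
from .metrics import MetricsReport, compute_metrics, confusion_counts, roc_auc
from .model import BiLstmConfig, FusionConfig, MultimodalNet, ViTConfig

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "SplitPlan", "focal_loss", "subject_split",
           "stratified_kfold", "AdamW", "train", "evaluate", "cross_validate"]

_EPS = 1e-12  # clamp on probabilities inside the focal loss


@dataclass
class TrainConfig:
    """Optimisation hyperparameters (study-scale defaults)."""

    epochs: int = 20
    learning_rate: float = 1e-4
    batch_size: int = 8
    weight_decay: float = 1e-5
    dropout: float = 0.5
    seed: int = 42
    focal_gamma: float = 2.0
    class_weight_mode: str = "inverse"  # or "none"

    def __post_init__(self):
        if min(self.epochs, self.batch_size) < 1 or self.learning_rate < 0:
            raise ValueError("invalid training hyperparameters")
        if self.class_weight_mode not in ("inverse", "none"):
            raise ValueError(f"unknown class_weight_mode {self.class_weight_mode!r}")

    @classmethod
    def tiny(cls, seed: int = 42):
        """From-scratch CPU preset: higher learning rate, a few more epochs.

        The study-scale learning rate targets fine-tuning a pretrained
        backbone; training the tiny random-init network from scratch needs a
        far larger step to move the logits off their initial scale within a
        few hundred optimiser steps.
        """
        return cls(epochs=30, learning_rate=3e-3, seed=seed)


@dataclass
class SplitPlan:
    train: list
    val: list
    test: list
    fractions: tuple = (0.55, 0.15, 0.30)

    def __post_init__(self):
        sets = [set(self.train), set(self.val), set(self.test)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("split sets must be pairwise disjoint")


def focal_loss(logits: Tensor, labels: np.ndarray, class_weights=None,
               gamma: float = 2.0) -> Tensor:
    """Mean over the batch of ``-w_y (1 - p_y)^gamma log p_y``.

    ``gamma = 0`` with unit weights reduces exactly to cross-entropy. The
    true-class probability is clamped at 1e-12 before the logarithm.
    """
    n = logits.shape[0]
    labels = np.asarray(labels).astype(int)
    logp = logits.log_softmax(axis=-1)[np.arange(n), labels].clip(float(np.log(_EPS)), 0.0)
    p = logp.exp()
    w = np.ones(n) if class_weights is None else np.asarray(class_weights, dtype=np.float64)[labels]
    loss = (-1.0 * Tensor(w)) * (1.0 - p) ** gamma * logp
    return loss.mean()


def class_weights(labels, mode: str = "inverse") -> np.ndarray:
    """Inverse-frequency class weights normalised to mean 1 (or uniform)."""
    labels = np.asarray(labels).astype(int)
    if mode == "none":
        return np.ones(2)
    counts = np.bincount(labels, minlength=2).astype(np.float64)
    if np.any(counts == 0):
        return np.ones(2)
    w = 1.0 / counts
    return w / w.mean()


def _largest_remainder(total_per_class: int, fractions) -> list:
    quotas = np.asarray(fractions, dtype=np.float64) * total_per_class
    counts = np.floor(quotas).astype(int)
    remainder = quotas - counts
    # allocate leftover seats by descending remainder; ties go to earlier sets
    for idx in sorted(range(len(fractions)), key=lambda i: (-remainder[i], i))[: total_per_class - counts.sum()]:
        counts[idx] += 1
    return counts.tolist()


def subject_split(subjects, labels, fractions=(0.55, 0.15, 0.30), seed: int = 42) -> SplitPlan:
    """Stratified participant-level train/val/test split.

    Per class, set sizes follow largest-remainder rounding of the fractional
    quotas, so each set's positive count is within one of exact proportion.
    """
    subjects = list(subjects)
    labels = np.asarray(labels).astype(int)
    if len(subjects) != len(labels):
        raise ValueError("subjects and labels differ in length")
    if abs(sum(fractions) - 1.0) > 1e-9 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    sets = ([], [], [])
    for cls in np.unique(labels):
        members = [s for s, l in zip(subjects, labels) if l == cls]
        rng.shuffle(members)
        counts = _largest_remainder(len(members), fractions)
        start = 0
        for si, c in enumerate(counts):
            sets[si].extend(members[start:start + c])
            start += c
    return SplitPlan(train=sets[0], val=sets[1], test=sets[2], fractions=tuple(fractions))


def stratified_kfold(subjects, labels, k: int = 10, seed: int = 42) -> list:
    """k disjoint subject folds; per-fold class counts within 1 of proportion.

    Requires every class to have at least k members, otherwise some fold would
    lack that class entirely.
    """
    subjects = list(subjects)
    labels = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    folds = [[] for _ in range(k)]
    offset = 0  # continue the round-robin deal across classes so total fold
    for cls in np.unique(labels):  # sizes stay within one of n/k as well
        members = [s for s, l in zip(subjects, labels) if l == cls]
        if len(members) < k:
            raise ValueError(
                f"class {cls} has {len(members)} subjects < k={k}; use fewer folds")
        rng.shuffle(members)
        for i, m in enumerate(members):
            folds[(offset + i) % k].append(m)
        offset = (offset + len(members)) % k
    return folds


class AdamW:
    """Adam with decoupled weight decay over a flat parameter list."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    best_epoch: int = -1
    seconds: float = 0.0


def _batch_loss(model, frames, tab, y, weights, gamma):
    logits = model(Tensor(frames), Tensor(tab))
    return focal_loss(logits, y, class_weights=weights, gamma=gamma)


def train(model: MultimodalNet, data: SequenceDataset, train_idx, val_idx,
          cfg: TrainConfig) -> TrainHistory:
    """Train on the given sequence indices; keep the best-validation weights.

    Deterministic given (model seed, cfg.seed): batch order is drawn from a
    dedicated generator and dropout noise from the model's own stream.
    """
    t0 = time.time()
    rng = np.random.default_rng(cfg.seed)
    train_idx = np.asarray(train_idx, dtype=int)
    val_idx = np.asarray(val_idx, dtype=int)
    weights = class_weights(data.y[train_idx], cfg.class_weight_mode)
    opt = AdamW(model.parameters(), lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    history = TrainHistory()
    best_val, best_state = np.inf, model.state_dict()
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            opt.zero_grad()
            loss = _batch_loss(model, data.frames[sel], data.tabular[sel],
                               data.y[sel], weights, cfg.focal_gamma)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss.data}")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.train_loss.append(float(np.mean(losses)) if losses else np.nan)
        model.eval()
        if len(val_idx):
            with no_grad():
                vloss = float(_batch_loss(model, data.frames[val_idx], data.tabular[val_idx],
                                          data.y[val_idx], weights, cfg.focal_gamma).data)
            if vloss < best_val:
                best_val, best_state = vloss, model.state_dict()
                history.best_epoch = epoch
        else:
            # no validation set: keep the final weights (train loss under
            # dropout is too noisy to select an epoch by)
            vloss = history.train_loss[-1]
            best_state = model.state_dict()
            history.best_epoch = epoch
        history.val_loss.append(vloss)
        logger.debug("epoch %d train %.4f val %.4f", epoch, history.train_loss[-1], vloss)
    model.load_state_dict(best_state)
    model.eval()
    history.seconds = time.time() - t0
    return history


def evaluate(model: MultimodalNet, data: SequenceDataset, idx,
             subject_level: bool = True) -> dict:
    """Metrics on the given sequences; subject level aggregates a subject's
    sequence probabilities by their mean before thresholding at 0.5."""
    idx = np.asarray(idx, dtype=int)
    probs = model.predict_proba(Tensor(data.frames[idx]).data, data.tabular[idx])[:, 1]
    seq_truth = data.y[idx]
    if subject_level:
        sub = data.subject_index[idx]
        positions = np.unique(sub)
        scores = np.array([probs[sub == p].mean() for p in positions])
        truth = data.subject_labels[positions]
    else:
        scores, truth = probs, seq_truth
    pred = (scores >= 0.5).astype(int)
    out = compute_metrics(confusion_counts(truth, pred))
    out["auc"] = roc_auc(scores, truth) if len(np.unique(truth)) == 2 else np.nan
    out["n"] = len(truth)
    return out


def _make_model(vit_cfg, lstm_cfg, fusion_cfg, tabular_dim, seed):
    return MultimodalNet(vit_cfg, lstm_cfg, fusion_cfg, tabular_dim, seed=seed)


def cross_validate(data: SequenceDataset, cfg: TrainConfig, fusion_kinds,
                   k: int = 10, vit_cfg: ViTConfig = None, lstm_cfg: BiLstmConfig = None,
                   d_k: int = 32, fusion_heads: int = 2,
                   subject_level: bool = True) -> dict:
    """Subject-level stratified k-fold comparison of fusion strategies.

    Each fold is the held-out subject set; the remaining subjects are split
    80/20 (stratified) into train/validation for early-model selection. A fold
    that fails to train is recorded and skipped; the run continues.
    Returns ``{fusion_kind: MetricsReport}``.
    """
    vit_cfg = vit_cfg or ViTConfig.tiny()
    lstm_cfg = lstm_cfg or BiLstmConfig(input_dim=vit_cfg.embed_dim, hidden=32, layers=1)
    positions = np.arange(len(data.subject_ids))
    folds = stratified_kfold(positions, data.subject_labels, k=k, seed=cfg.seed)
    reports = {}
    for kind in fusion_kinds:
        report = MetricsReport(name=kind)
        for fi, test_subjects in enumerate(folds):
            try:
                rest = np.array(sorted(set(positions) - set(test_subjects)))
                inner = subject_split(rest, data.subject_labels[rest],
                                      fractions=(0.8, 0.2, 0.0), seed=cfg.seed + fi)
                fusion_cfg = FusionConfig(kind=kind, d_k=d_k, heads=fusion_heads,
                                          dropout=cfg.dropout)
                model = _make_model(vit_cfg, lstm_cfg, fusion_cfg,
                                    data.tabular.shape[1], seed=cfg.seed + fi)
                train(model, data, data.select_subjects(inner.train),
                      data.select_subjects(inner.val), cfg)
                fold_metrics = evaluate(model, data, data.select_subjects(test_subjects),
                                        subject_level=subject_level)
                if not np.isfinite(fold_metrics.get("auc", np.nan)):
                    fold_metrics["auc"] = 0.5  # single-class fold: uninformative
                report.add_fold(fold_metrics)
            except Exception as exc:  # noqa: BLE001 - a failed fold must not kill the run
                logger.warning("fold %d failed for %s: %s", fi, kind, exc)
                report.failed_folds.append({"fold": fi, "error": str(exc)})
        if report.failed_folds:
            logger.warning("%s: %d/%d folds failed", kind, len(report.failed_folds), k)
        reports[kind] = report
    return reports
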