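"""Episodic meta-training with leave-one-subject-out episodes.

Each training epoch consists of one episode per training subject: that
subject supplies a class-stratified query batch (default 12 trials, at
least one target) and every other training subject contributes support
trials from which per-subject class-mean features and prototypes are
built.  The held-out *test* subject is outside this function entirely -
``fit`` only ever sees training subjects, which is what makes the
protocol zero-calibration.

Optimization: Adam (beta1 = 0.9), learning rate 1e-4 by default, with
cosine annealing to 1/100 of the base rate over the scheduled epochs and
optional early stopping on a rotating-validation balanced-accuracy
plateau.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn, protonet
from .data_io import SubjectCollection, ValidationError
from .encoder import Encoder, EncoderConfig, build_encoder
from .protonet import AttentionProtoNet, LossBreakdown

__all__ = ["TrainConfig", "EpisodeSpec", "make_episodes", "train_step", "fit",
           "FitResult"]


@dataclass
class TrainConfig:
    epochs: int = 50
    query_size: int = 12
    lr: float = 1e-4
    optimizer: str = "adam"
    scheduler: bool = True              # cosine annealing on/off
    lambda_metric: float = 1.0
    seed: int = 0
    device: str = "cpu"
    support_cap: int = 200              # max support trials per subject/episode
    alpha_per: str = "sample"           # subject attention per "sample"|"batch"
    early_stopping: bool = True
    patience: int = 10

    def validate(self) -> None:
        if self.query_size < 1:
            raise ValidationError(f"query_size must be >= 1, got {self.query_size}")
        if self.lr <= 0:
            raise ValidationError(f"lr must be positive, got {self.lr}")
        if self.optimizer != "adam":
            raise ValidationError(f"only 'adam' is supported, got {self.optimizer}")
        if self.device != "cpu":
            raise ValidationError(f"only 'cpu' is supported, got {self.device}")
        if self.alpha_per not in ("sample", "batch"):
            raise ValidationError(f"alpha_per must be 'sample' or 'batch'")


@dataclass
class EpisodeSpec:
    query_subject: str
    support_subjects: list[str]
    query_trial_indices: np.ndarray

    def __post_init__(self):
        if self.query_subject in self.support_subjects:
            raise ValidationError(
                f"query subject {self.query_subject!r} appears in its own support")
        idx = np.asarray(self.query_trial_indices)
        if len(np.unique(idx)) != len(idx):
            raise ValidationError("query trial indices must be unique")


def _stratified_query(labels: np.ndarray, size: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Sample query indices with the class mix of the subject, >= 1 target."""
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if pos.size == 0:
        raise ValidationError("subject has no target trials")
    n_pos = min(max(int(round(size * pos.size / labels.size)), 1), pos.size)
    n_neg = min(size - n_pos, neg.size)
    chosen = np.concatenate([rng.choice(pos, n_pos, replace=False),
                             rng.choice(neg, n_neg, replace=False)])
    rng.shuffle(chosen)
    return chosen


def make_episodes(data: SubjectCollection, epoch_index: int,
                  config: TrainConfig, rng: np.random.Generator
                  ) -> list[EpisodeSpec]:
    """One episode per training subject, order shuffled; each subject serves
    as query exactly once per epoch."""
    sids = data.subject_ids
    if len(sids) < 2:
        raise ValidationError("episodic training needs at least 2 subjects")
    order = list(rng.permutation(sids))
    episodes = []
    for sid in order:
        support = [s for s in sids if s != sid]
        q_idx = _stratified_query(data[sid].labels, config.query_size, rng)
        episodes.append(EpisodeSpec(query_subject=sid, support_subjects=support,
                                    query_trial_indices=q_idx))
    return episodes


def _capped_support(labels: np.ndarray, cap: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Class-balanced subsample of a support subject's trials.

    Equal counts per class (up to cap/2 each, limited by availability).
    Balancing matters: prototypes are class means, and with the 1:24
    oddball imbalance an unbalanced draw gives the target prototype far
    higher sampling variance, which biases every query's distance
    comparison toward the nontarget class.
    """
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    n = min(pos.size, neg.size, max(cap // 2, 1))
    return np.concatenate([rng.choice(pos, n, replace=False),
                           rng.choice(neg, n, replace=False)])


def _episode_tensors(model: AttentionProtoNet, episode: EpisodeSpec,
                     data: SubjectCollection, config: TrainConfig,
                     rng: np.random.Generator, training: bool):
    """Encode support + query in one training-mode batch; return per-subject
    class means (m, 2, 1024), query features (q, 1024), query labels."""
    blocks, slices, pos_masks = [], [], []
    start = 0
    for sid in episode.support_subjects:
        es = data[sid]
        if not (es.labels == 1).any() or not (es.labels == 0).any():
            raise ValidationError(
                f"support subject {sid!r} lacks trials of one class")
        idx = _capped_support(es.labels, config.support_cap, rng)
        blocks.append(es.data[idx])
        pos_masks.append(es.labels[idx] == 1)
        slices.append((start, start + len(idx)))
        start += len(idx)
    q_es = data[episode.query_subject]
    q_idx = np.asarray(episode.query_trial_indices)
    blocks.append(q_es.data[q_idx])
    q_slice = (start, start + len(q_idx))

    batch = np.concatenate(blocks, axis=0)
    model.encoder.train(training)
    feats = model.encoder.forward(nn.Tensor(batch))       # (n, 1024) Tensor

    class_mean_rows = []
    for (lo, hi), pos in zip(slices, pos_masks):
        sub = feats[lo:hi]
        neg_mean = sub[np.flatnonzero(~pos)].mean(axis=0)
        pos_mean = sub[np.flatnonzero(pos)].mean(axis=0)
        class_mean_rows.append(neg_mean.reshape(1, protonet.FEATURE_DIM))
        class_mean_rows.append(pos_mean.reshape(1, protonet.FEATURE_DIM))
    m = len(slices)
    class_means = nn.concat(class_mean_rows, axis=0).reshape(
        m, 2, protonet.FEATURE_DIM)
    query_feats = feats[q_slice[0]:q_slice[1]]
    return class_means, query_feats, q_es.labels[q_idx]


def train_step(model: AttentionProtoNet, episode: EpisodeSpec,
               data: SubjectCollection, config: TrainConfig,
               optimizer: nn.Adam, rng: np.random.Generator) -> LossBreakdown:
    """One episode: forward, backward, one optimizer step.

    Returns the losses measured *before* the parameter update.
    """
    model.train(True)
    class_means, query_feats, q_labels = _episode_tensors(
        model, episode, data, config, rng, training=True)
    dists, alpha, z = model.episode_forward(class_means, query_feats,
                                            alpha_per=config.alpha_per)
    class_loss, metric, total = model.losses(dists, q_labels,
                                             config.lambda_metric)
    breakdown = LossBreakdown(class_loss=class_loss.item(),
                              metric_loss=metric.item(),
                              total=total.item())
    if not np.isfinite(breakdown.total):
        raise RuntimeError(
            "non-finite loss in episode with query subject "
            f"{episode.query_subject!r}: class={breakdown.class_loss}, "
            f"metric={breakdown.metric_loss}")
    optimizer.zero_grad()
    total.backward()
    optimizer.step()
    return breakdown


@dataclass
class FitResult:
    model: AttentionProtoNet
    log: list[dict] = field(default_factory=list)
    stopped_epoch: int | None = None

    def write_log(self, path) -> None:
        path = Path(path)
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=[
                "epoch", "episode", "query_subject", "class_loss",
                "metric_loss", "total", "lr"])
            writer.writeheader()
            writer.writerows(self.log)


def fit(data: SubjectCollection, config: TrainConfig,
        encoder_config: EncoderConfig | None = None,
        feature_attention: bool = True, subject_attention: bool = True,
        model: AttentionProtoNet | None = None) -> FitResult:
    """Meta-train on a collection of training subjects.

    The held-out test subject must not be part of ``data``; evaluation
    lives in :mod:`protoerp.evaluate`.
    """
    config.validate()
    if len(data) < 2:
        raise ValidationError("fit needs at least 2 training subjects")
    if model is None:
        enc_cfg = encoder_config or EncoderConfig()
        encoder = build_encoder(enc_cfg, data.n_channels, data.n_samples,
                                seed=config.seed, sfreq=data.sfreq)
        model = AttentionProtoNet(encoder,
                                  feature_attention=feature_attention,
                                  subject_attention=subject_attention,
                                  seed=config.seed)
    optimizer = nn.Adam(model.parameters(), lr=config.lr)
    rng = np.random.Generator(np.random.Philox([config.seed, 0xEF]))
    result = FitResult(model=model)
    best_ba, best_epoch = -np.inf, 0
    sids = data.subject_ids

    for epoch in range(config.epochs):
        lr = nn.cosine_lr(config.lr, epoch, config.epochs) \
            if config.scheduler else config.lr
        optimizer.lr = lr
        episodes = make_episodes(data, epoch, config, rng)
        for ep_i, episode in enumerate(episodes):
            breakdown = train_step(model, episode, data, config, optimizer, rng)
            result.log.append({
                "epoch": epoch, "episode": ep_i,
                "query_subject": episode.query_subject,
                "class_loss": breakdown.class_loss,
                "metric_loss": breakdown.metric_loss,
                "total": breakdown.total, "lr": lr,
            })
        if config.early_stopping and len(sids) >= 3:
            from .evaluate import zero_calibration_eval

            val_sid = sids[epoch % len(sids)]
            rest = data.subset([s for s in sids if s != val_sid])
            report = zero_calibration_eval(model, rest, data[val_sid])
            if report.ba > best_ba + 1e-6:
                best_ba, best_epoch = report.ba, epoch
            elif epoch - best_epoch >= config.patience:
                result.stopped_epoch = epoch
                break
    return result
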