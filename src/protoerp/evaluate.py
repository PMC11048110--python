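"""Zero-calibration evaluation and class-imbalance-aware metrics.

Balanced accuracy BA = (TPR + TNR) / 2 is the primary metric for the
1 : 24 oddball imbalance (0.5 = chance for any label-independent
classifier).  AUC is computed rank-based (Mann-Whitney; ties count 1/2),
and subject-level paired comparisons use the two-sided Wilcoxon
signed-rank test.

``zero_calibration_eval`` scores a held-out subject: support prototypes
and attention come only from training subjects (encoder in eval mode,
running batch-norm statistics), and no test trial influences the model
or the prototypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata, wilcoxon

from . import nn, protonet
from .data_io import EpochSet, SubjectCollection, ValidationError
from .protonet import AttentionProtoNet

__all__ = ["MetricsReport", "balanced_accuracy", "auc", "paired_wilcoxon",
           "zero_calibration_eval", "loso", "significance_stars"]


@dataclass
class MetricsReport:
    ba: float
    tpr: float
    tnr: float
    tp: int
    fp: int
    fn: int
    tn: int
    n: int
    auc: float | None = None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("ba", "auc", "tpr", "tnr", "tp", "fp", "fn", "tn", "n")}


def balanced_accuracy(labels: np.ndarray, predictions: np.ndarray) -> MetricsReport:
    """Confusion counts, TPR, TNR and BA = (TPR + TNR) / 2."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValidationError(
            f"labels {labels.shape} and predictions {predictions.shape} differ")
    if not ((labels == 1).any() and (labels == 0).any()):
        raise ValidationError("balanced accuracy needs both classes in labels")
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))
    tn = int(np.sum((labels == 0) & (predictions == 0)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    tpr = tp / (tp + fn)
    tnr = tn / (tn + fp)
    return MetricsReport(ba=0.5 * (tpr + tnr), tpr=tpr, tnr=tnr,
                         tp=tp, fp=fp, fn=fn, tn=tn, n=labels.size)


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based Mann-Whitney AUC of ``scores`` for class 1; ties give 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        raise ValidationError("AUC needs both classes in labels")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def paired_wilcoxon(metric_a: np.ndarray, metric_b: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value over paired subject metrics.

    Zero differences are dropped (Wilcoxon convention); if every pair is
    tied the test is undefined and p = 1 is returned with a warning.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"paired vectors differ in shape: {a.shape} vs {b.shape}")
    if a.size < 5:
        raise ValidationError("paired Wilcoxon needs at least 5 subjects")
    if np.all(a == b):
        warnings.warn("all paired differences are zero; p-value set to 1")
        return 1.0
    return float(wilcoxon(a, b, zero_method="wilcox",
                          alternative="two-sided").pvalue)


def significance_stars(p: float) -> str:
    """Star notation at the usual 0.05 / 0.01 / 0.001 thresholds."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _support_state(model: AttentionProtoNet, train_subjects: SubjectCollection,
                   chunk: int = 256):
    """Per-subject class-mean features and feature-attention scores (eval mode)."""
    model.train(False)
    means = []
    for sid in train_subjects.subject_ids:
        es = train_subjects[sid]
        if not (es.labels == 1).any() or not (es.labels == 0).any():
            raise ValidationError(f"support subject {sid!r} lacks one class")
        with nn.no_grad():
            parts = [model.encoder.forward(nn.Tensor(es.data[i:i + chunk])).data
                     for i in range(0, es.n_trials, chunk)]
        feats = np.concatenate(parts, axis=0)
        means.append(np.stack([feats[es.labels == 0].mean(axis=0),
                               feats[es.labels == 1].mean(axis=0)]))
    class_means = np.stack(means)                        # (m, 2, 1024)
    if model.use_feature_attention:
        z = protonet.feature_attention(class_means.mean(axis=0),
                                       model.fa_weight.data,
                                       float(model.fa_bias.data[0]))
    else:
        z = np.ones((2, protonet.FEATURE_DIM))
    return class_means, z


def zero_calibration_eval(model: AttentionProtoNet,
                          train_subjects: SubjectCollection,
                          test_subject: EpochSet,
                          chunk: int = 256) -> MetricsReport:
    """Score every trial of an unseen subject with prototypes built from
    training subjects only."""
    if test_subject.subject_id in train_subjects.subject_ids:
        raise ValidationError(
            f"test subject {test_subject.subject_id!r} overlaps the training set")
    class_means, z = _support_state(model, train_subjects, chunk)
    subject_means = class_means.mean(axis=1)             # (m, 1024)
    g = model.g.weight.data if model.use_subject_attention else None

    model.train(False)
    with nn.no_grad():
        parts = [model.encoder.forward(
            nn.Tensor(test_subject.data[i:i + chunk])).data
            for i in range(0, test_subject.n_trials, chunk)]
    query = np.concatenate(parts, axis=0)                # (n, 1024)

    alpha = protonet.subject_attention(subject_means, query, g,
                                       enabled=model.use_subject_attention)
    alpha = np.atleast_2d(alpha)                         # (n, m)
    protos = np.tensordot(alpha, class_means, axes=(1, 0))   # (n, 2, 1024)
    diff = query[:, None, :] - protos
    dists = np.einsum("kj,nkj->nk", z, diff * diff)      # (n, 2)
    preds = (dists[:, 1] < dists[:, 0]).astype(np.int64)

    report = balanced_accuracy(test_subject.labels, preds)
    # ranking score: d0 - d1 is a strictly monotone transform of P(y=1)
    # (AUC-equivalent) with better resolution once the softmax saturates
    report.auc = auc(test_subject.labels, dists[:, 0] - dists[:, 1])
    return report


def loso(data: SubjectCollection, fit_fn) -> dict[str, MetricsReport]:
    """Leave-one-subject-out driver.

    ``fit_fn(train_collection) -> model``; each subject is held out exactly
    once and never enters its own training collection.
    """
    reports: dict[str, MetricsReport] = {}
    for sid in data.subject_ids:
        train_coll = data.subset([s for s in data.subject_ids if s != sid])
        model = fit_fn(train_coll)
        reports[sid] = zero_calibration_eval(model, train_coll, data[sid])
    return reports
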