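"""Prototype matching with hybrid (feature- and subject-level) attention.

The decoder represents each class (target / nontarget) by a prototype in
the 1024-dimensional encoder feature space.  Per-subject class-mean
features are combined into prototypes with subject-level attention
weights ``alpha`` (softmax over support subjects, per query sample), and
query-to-prototype distances are squared Euclidean distances weighted
per dimension by feature-level attention scores ``z_k``:

    d(f, p_k) = sum_j z_k[j] * (f[j] - p_k[j])^2

With both attentions disabled (``alpha`` uniform, ``z_k = 1``) the model
reduces exactly to a plain prototype network with unweighted class means
and squared Euclidean distance.

Class probabilities come from a softmax over *negative* distances, so the
nearer prototype receives the larger probability.  The training objective
is mean binary cross-entropy plus ``lambda_metric`` times a metric term,
mean(d_to_true_class - d_to_other_class), which pulls samples toward
their own prototype and pushes them from the other.

This module has two faces: plain NumPy functions implementing each
operation (used at evaluation time and as readable reference), and an
autograd head (:class:`AttentionProtoNet`) used by the trainer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .encoder import Encoder

__all__ = [
    "PrototypePair", "AttentionState", "LossBreakdown",
    "subject_attention", "compute_prototypes", "feature_attention",
    "weighted_distance", "class_probabilities", "classification_loss",
    "metric_loss", "total_loss", "classify", "AttentionProtoNet",
]

FEATURE_DIM = 1024
PROB_CLIP = 1e-12


@dataclass
class PrototypePair:
    p0: np.ndarray   # nontarget prototype (1024,)
    p1: np.ndarray   # target prototype (1024,)

    def __post_init__(self):
        for name, p in (("p0", self.p0), ("p1", self.p1)):
            if not np.isfinite(p).all():
                raise ValueError(f"{name} contains non-finite values")

    def stack(self) -> np.ndarray:
        return np.stack([self.p0, self.p1])


@dataclass
class AttentionState:
    """Feature weights per class and subject weights for one query."""

    z0: np.ndarray       # (1024,), nonnegative, mean 1
    z1: np.ndarray
    alpha: np.ndarray    # (n_support_subjects,), nonnegative, sums to 1


@dataclass
class LossBreakdown:
    class_loss: float
    metric_loss: float
    total: float


# ---------------------------------------------------------------------------
# functional reference implementations (NumPy)
# ---------------------------------------------------------------------------


def subject_attention(support_features: np.ndarray, query_feature: np.ndarray,
                      g: np.ndarray | None, enabled: bool = True) -> np.ndarray:
    """Attention weights over support subjects for one (or more) queries.

    ``support_features``: (m, 1024) per-subject mean features;
    ``query_feature``: (1024,) or (q, 1024); ``g``: the (1024, 1024) matrix
    of the shared linear map (ignored when disabled).

    Per subject k: ``e_k = sum_j tanh( (g f_k) * (g f_query) )_j`` and
    ``alpha = softmax(e)``.  Returns (m,) or (q, m).
    """
    support_features = np.asarray(support_features)
    m = support_features.shape[0]
    query = np.atleast_2d(np.asarray(query_feature))
    if not enabled:
        alpha = np.full((query.shape[0], m), 1.0 / m)
        return alpha[0] if np.asarray(query_feature).ndim == 1 else alpha
    if g is None:
        raise ValueError("subject attention enabled but no linear map given")
    if support_features.shape[1] != g.shape[0] or query.shape[1] != g.shape[0]:
        raise ValueError(
            f"dimension mismatch: features {support_features.shape[1]} vs "
            f"map {g.shape}")
    gs = support_features @ g          # (m, 1024)
    gq = query @ g                     # (q, 1024)
    e = np.tanh(gq[:, None, :] * gs[None, :, :]).sum(axis=-1)   # (q, m)
    e = e - e.max(axis=1, keepdims=True)
    alpha = np.exp(e)
    alpha /= alpha.sum(axis=1, keepdims=True)
    return alpha[0] if np.asarray(query_feature).ndim == 1 else alpha


def compute_prototypes(per_subject_class_means: np.ndarray,
                       alpha: np.ndarray) -> PrototypePair:
    """Attention-weighted prototypes from per-subject class means.

    ``per_subject_class_means``: (m, 2, 1024); ``alpha``: (m,) summing to 1.
    With uniform alpha this is the plain unweighted mean over subjects.
    """
    means = np.asarray(per_subject_class_means)
    alpha = np.asarray(alpha)
    if alpha.shape[0] != means.shape[0]:
        raise ValueError(
            f"alpha length {alpha.shape[0]} != n_support_subjects {means.shape[0]}")
    if not np.isclose(alpha.sum(), 1.0, atol=1e-6):
        raise ValueError(f"alpha must sum to 1, got {alpha.sum()}")
    p = np.tensordot(alpha, means, axes=(0, 0))     # (2, 1024)
    return PrototypePair(p0=p[0], p1=p[1])


def feature_attention(class_mean_features: np.ndarray, conv_weight: np.ndarray,
                      conv_bias: float = 0.0, enabled: bool = True) -> np.ndarray:
    """Per-dimension attention scores for each class.

    ``class_mean_features``: (2, 1024) support class-mean features.  A 1-D
    convolution (kernel ``conv_weight``, 'same' padding) over the feature
    vector followed by ReLU gives logits; a softmax over the 1024
    dimensions scaled by 1024 yields z_k with mean exactly 1.  Disabled ->
    all-ones (recovers plain squared Euclidean distance).
    """
    means = np.atleast_2d(np.asarray(class_mean_features, dtype=float))
    if not enabled:
        return np.ones_like(means)
    w = np.asarray(conv_weight, dtype=float).ravel()
    k = w.size
    pl = (k - 1) // 2
    padded = np.pad(means, ((0, 0), (pl, k - 1 - pl)), mode="constant")
    windows = np.lib.stride_tricks.sliding_window_view(padded, k, axis=1)
    logits = np.maximum(windows @ w + conv_bias, 0.0)
    logits = logits - logits.max(axis=1, keepdims=True)
    z = np.exp(logits)
    z = z / z.sum(axis=1, keepdims=True) * means.shape[1]
    return z


def weighted_distance(f: np.ndarray, p_k: np.ndarray, z_k: np.ndarray) -> float:
    """Feature-weighted squared Euclidean distance sum_j z[j] (f[j]-p[j])^2."""
    f, p_k, z_k = (np.asarray(a, dtype=float) for a in (f, p_k, z_k))
    if (z_k < 0).any():
        raise ValueError("feature-attention weights must be nonnegative")
    diff = f - p_k
    return float(np.sum(z_k * diff * diff, axis=-1)) if diff.ndim == 1 \
        else np.sum(z_k * diff * diff, axis=-1)


def class_probabilities(d0, d1) -> tuple:
    """Softmax over negative distances: the nearer prototype wins.

    Accepts scalars or arrays; returns (P(y=0), P(y=1)).
    """
    d0 = np.asarray(d0, dtype=float)
    d1 = np.asarray(d1, dtype=float)
    m = np.minimum(d0, d1)
    e0 = np.exp(-(d0 - m))
    e1 = np.exp(-(d1 - m))
    s = e0 + e1
    p0, p1 = e0 / s, e1 / s
    if p0.ndim == 0:
        return float(p0), float(p1)
    return p0, p1


def classification_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy.

    ``probs``: (n, 2) columns (P(y=0), P(y=1)); probabilities are clipped
    at ``PROB_CLIP`` before the log.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if probs.shape[0] != labels.shape[0]:
        raise ValueError(
            f"probs rows {probs.shape[0]} != labels length {labels.shape[0]}")
    p = np.clip(np.where(labels == 1, probs[:, 1], probs[:, 0]), PROB_CLIP, 1.0)
    return float(-np.mean(np.log(p)))


def metric_loss(distances_same: np.ndarray, distances_other: np.ndarray) -> float:
    """Mean (d_to_true_class - d_to_other_class): negative is good."""
    ds = np.asarray(distances_same, dtype=float)
    do = np.asarray(distances_other, dtype=float)
    return float(np.mean(ds - do))


def total_loss(class_loss: float, metric: float,
               lambda_metric: float = 1.0) -> LossBreakdown:
    if lambda_metric < 0:
        raise ValueError(f"lambda_metric must be >= 0, got {lambda_metric}")
    return LossBreakdown(class_loss=float(class_loss), metric_loss=float(metric),
                         total=float(class_loss) + lambda_metric * float(metric))


def classify(query_features: np.ndarray, prototypes: PrototypePair,
             z0: np.ndarray | None = None, z1: np.ndarray | None = None):
    """Nearest-prototype labels and probabilities for a query batch.

    Ties break toward class 0 (nontarget).  Returns (labels, probs) with
    probs of shape (n, 2).
    """
    q = np.atleast_2d(np.asarray(query_features, dtype=float))
    dim = q.shape[1]
    z0 = np.ones(dim) if z0 is None else np.asarray(z0)
    z1 = np.ones(dim) if z1 is None else np.asarray(z1)
    d0 = np.sum(z0 * (q - prototypes.p0) ** 2, axis=1)
    d1 = np.sum(z1 * (q - prototypes.p1) ** 2, axis=1)
    p0, p1 = class_probabilities(d0, d1)
    labels = (d1 < d0).astype(np.int64)
    return labels, np.column_stack([np.atleast_1d(p0), np.atleast_1d(p1)])


# ---------------------------------------------------------------------------
# trainable model (autograd)
# ---------------------------------------------------------------------------


class AttentionProtoNet(nn.Module):
    """Encoder + hybrid-attention prototype head.

    ``feature_attention`` / ``subject_attention`` toggles reproduce the
    ablation patterns; with both off this is a plain prototype network.
    """

    def __init__(self, encoder: Encoder, feature_attention: bool = True,
                 subject_attention: bool = True, fa_kernel: int = 9,
                 seed: int = 0):
        super().__init__()
        if fa_kernel % 2 == 0:
            raise ValueError(f"feature-attention kernel must be odd, got {fa_kernel}")
        rng = np.random.Generator(np.random.Philox([seed, 0xA7]))
        self.encoder = encoder
        self.use_feature_attention = feature_attention
        self.use_subject_attention = subject_attention
        self.g = nn.Linear(FEATURE_DIM, FEATURE_DIM, rng) \
            if subject_attention else None
        if feature_attention:
            self.fa_weight = nn.Parameter(
                rng.normal(0.0, 1.0 / np.sqrt(fa_kernel), size=(1, fa_kernel)))
            self.fa_bias = nn.Parameter(np.zeros(1))

    # pieces (Tensor-valued, used by the trainer) -------------------------

    def feature_attention_t(self, class_means: nn.Tensor) -> nn.Tensor:
        """(2, 1024) class means -> (2, 1024) scores with mean 1."""
        if not self.use_feature_attention:
            return nn.Tensor(np.ones(class_means.shape))
        c, dim = class_means.shape
        conv = nn.temporal_conv(class_means.reshape(c, 1, dim), self.fa_weight)
        logits = (conv.reshape(c, dim) + self.fa_bias).relu()
        return logits.softmax(axis=1) * float(dim)

    def subject_attention_t(self, subject_means: nn.Tensor,
                            query: nn.Tensor) -> nn.Tensor:
        """(m, 1024) subject means, (q, 1024) queries -> (q, m) alpha."""
        m = subject_means.shape[0]
        q = query.shape[0]
        if not self.use_subject_attention:
            return nn.Tensor(np.full((q, m), 1.0 / m))
        gs = self.g(subject_means)      # (m, 1024)
        gq = self.g(query)              # (q, 1024)
        prod = gq.reshape(q, 1, FEATURE_DIM) * gs.reshape(1, m, FEATURE_DIM)
        e = prod.tanh().sum(axis=-1)    # (q, m)
        return e.softmax(axis=1)

    def episode_forward(self, support_class_means: nn.Tensor,
                        query_features: nn.Tensor,
                        alpha_per: str = "sample") -> tuple:
        """Distances of each query to both prototypes.

        ``support_class_means``: (m, 2, 1024); ``query_features``: (q, 1024).
        Returns (distances (q, 2), alpha (q, m), z (2, 1024)).
        """
        m = support_class_means.shape[0]
        q = query_features.shape[0]
        subject_means = support_class_means.mean(axis=1)     # (m, 1024)
        class_means = support_class_means.mean(axis=0)       # (2, 1024)
        z = self.feature_attention_t(class_means)
        alpha = self.subject_attention_t(subject_means, query_features)
        if alpha_per == "batch":
            alpha = alpha.mean(axis=0, keepdims=True)
            ones = nn.Tensor(np.ones((q, 1)))
            alpha = ones @ alpha
        # prototypes per query: (q, 2, 1024)
        flat = support_class_means.reshape(m, 2 * FEATURE_DIM)
        protos = (alpha @ flat).reshape(q, 2, FEATURE_DIM)
        diff = query_features.reshape(q, 1, FEATURE_DIM) - protos
        dists = (z.reshape(1, 2, FEATURE_DIM) * diff * diff).sum(axis=-1)
        return dists, alpha, z

    def losses(self, dists: nn.Tensor, labels: np.ndarray,
               lambda_metric: float) -> tuple:
        """(class_loss, metric_loss, total) as Tensors from (q, 2) distances."""
        neg = -dists
        logp = neg - neg.logsumexp(axis=1, keepdims=True)    # (q, 2) log-probs
        # same probability floor as classification_loss (clip at PROB_CLIP)
        logp = logp.clip(np.log(PROB_CLIP), 0.0)
        idx = (np.arange(len(labels)), np.asarray(labels))
        class_loss = -(logp[idx].mean())
        other = 1 - np.asarray(labels)
        d_same = dists[(np.arange(len(labels)), np.asarray(labels))]
        d_other = dists[(np.arange(len(labels)), other)]
        metric = (d_same - d_other).mean()
        return class_loss, metric, class_loss + lambda_metric * metric
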