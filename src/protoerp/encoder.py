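"""Multiscale convolutional EEG encoder with channel-recalibration attention.

Maps one epoch (channels x time) to a 1024-dimensional batch-normalized
feature vector.  The architecture follows the EEGNet lineage, extended
with a multiscale first stage and two attention blocks:

* Block 1 - three parallel temporal convolutions at different kernel
  lengths (given in seconds, converted to odd sample counts), concatenated
  along the map axis; squeeze-and-excitation (SE) recalibration over the
  maps; a depthwise spatial convolution collapsing the electrode axis
  (``depth_multiplier`` filters per map); batch norm; ELU; average
  pooling; dropout.
* Block 2 - depthwise temporal convolution (16 samples); efficient channel
  attention (ECA: a shared 1-D convolution over the per-map descriptors)
  in place of a pointwise convolution; batch norm; ELU; average pooling;
  dropout.
* Head - flatten, one linear map to 1024, batch norm (no activation).

``variant="plain"`` disables the SE and ECA blocks, leaving a plain
multiscale convolutional encoder (the ablation baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .data_io import EpochSet

__all__ = ["EncoderConfig", "Encoder", "FeatureBatch", "build_encoder", "encode",
           "ConfigError", "ShapeError"]

OUT_DIM = 1024


class ConfigError(ValueError):
    """Invalid encoder configuration."""


class ShapeError(ValueError):
    """Input does not match the encoder's expected (channels, samples)."""


@dataclass
class EncoderConfig:
    temporal_kernels_s: list[float] = field(
        default_factory=lambda: [0.256, 0.128, 0.064])
    filters_per_branch: int = 8
    se_reduction: int = 4
    depth_multiplier: int = 2
    eca_kernel: int = 3
    pool1: int = 4
    pool2: int = 8
    dropout: float = 0.25
    out_dim: int = OUT_DIM
    variant: str = "incepa"          # "incepa" | "plain"

    def validate(self) -> None:
        if self.out_dim != OUT_DIM:
            raise ConfigError(f"out_dim is fixed at {OUT_DIM}, got {self.out_dim}")
        if self.eca_kernel % 2 == 0:
            raise ConfigError(f"eca_kernel must be odd, got {self.eca_kernel}")
        if not self.temporal_kernels_s:
            raise ConfigError("need at least one temporal kernel")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.variant not in ("incepa", "plain"):
            raise ConfigError(f"variant must be 'incepa' or 'plain', got {self.variant}")

    def kernel_samples(self, sfreq: float) -> list[int]:
        out = []
        for ks in self.temporal_kernels_s:
            k = max(int(round(ks * sfreq)), 1)
            if k % 2 == 0:
                k += 1
            out.append(k)
        return out


@dataclass
class FeatureBatch:
    """Encoder outputs with their provenance carried alongside."""

    features: np.ndarray                 # (n, 1024)
    labels: np.ndarray | None = None     # (n,)
    subject_ids: list[str] | None = None


class _SqueezeExcite(nn.Module):
    def __init__(self, n_maps: int, reduction: int, rng):
        super().__init__()
        hidden = max(n_maps // reduction, 1)
        self.fc1 = nn.Linear(n_maps, hidden, rng)
        self.fc2 = nn.Linear(hidden, n_maps, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        # x: (N, M, C, T) -> per-map descriptor -> sigmoid gate
        s = x.mean(axis=(2, 3))
        gate = self.fc2(self.fc1(s).relu()).sigmoid()
        n, m = gate.shape
        return x * gate.reshape(n, m, 1, 1)


class _ECA(nn.Module):
    """Efficient channel attention: shared 1-D conv over map descriptors."""

    def __init__(self, kernel: int, rng):
        super().__init__()
        self.weight = nn.Parameter(rng.normal(0.0, 1.0 / np.sqrt(kernel),
                                              size=(1, kernel)))

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        # x: (N, M, T); descriptor s: (N, M); conv over the M axis
        s = x.mean(axis=2)
        n, m = s.shape
        conv = nn.temporal_conv(s.reshape(n, 1, m), self.weight)  # (N,1,1,M)
        gate = conv.reshape(n, m).sigmoid()
        return x * gate.reshape(n, m, 1)


class Encoder(nn.Module):
    """See module docstring for the block structure."""

    def __init__(self, config: EncoderConfig, n_channels: int, n_samples: int,
                 sfreq: float, seed: int):
        super().__init__()
        config.validate()
        kernels = config.kernel_samples(sfreq)
        for k in kernels:
            if k > n_samples:
                raise ConfigError(
                    f"temporal kernel of {k} samples exceeds the epoch length "
                    f"{n_samples}")
        if 16 > n_samples:
            raise ConfigError("epoch too short for the 16-sample block-2 kernel")

        self.config = config
        self.n_channels = n_channels
        self.n_samples = n_samples
        self.sfreq = sfreq
        self.seed = seed
        init = np.random.Generator(np.random.Philox(seed))
        self._dropout_rng = np.random.Generator(np.random.Philox([seed, 0xD0]))

        F1, D = config.filters_per_branch, config.depth_multiplier
        self.branch_weights = [
            nn.Parameter(init.normal(0.0, 1.0 / np.sqrt(k), size=(F1, k)))
            for k in kernels
        ]
        m1 = F1 * len(kernels)
        self.use_attention = config.variant == "incepa"
        if self.use_attention:
            self.se = _SqueezeExcite(m1, config.se_reduction, init)
        self.spatial = nn.Parameter(
            init.normal(0.0, 1.0 / np.sqrt(n_channels), size=(m1, D, n_channels)))
        m2 = m1 * D
        self.bn1 = nn.BatchNorm(m2, feature_axis=1)
        self.drop1 = nn.Dropout(config.dropout, self._dropout_rng)

        self.dw_time = nn.Parameter(init.normal(0.0, 0.25, size=(m2, 16)))
        if self.use_attention:
            self.eca = _ECA(config.eca_kernel, init)
        self.bn2 = nn.BatchNorm(m2, feature_axis=1)
        self.drop2 = nn.Dropout(config.dropout, self._dropout_rng)

        t1 = n_samples // config.pool1
        t2 = t1 // config.pool2
        if t2 < 1:
            raise ConfigError(
                f"pooling ({config.pool1} x {config.pool2}) leaves no samples "
                f"from an epoch of {n_samples}")
        self.flat_dim = m2 * t2
        self.head = nn.Linear(self.flat_dim, config.out_dim, init)
        self.bn3 = nn.BatchNorm(config.out_dim, feature_axis=1)

    # forward --------------------------------------------------------------

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        """(N, C, T) -> (N, 1024)."""
        if x.shape[1:] != (self.n_channels, self.n_samples):
            raise ShapeError(
                f"expected epochs of shape (n, {self.n_channels}, "
                f"{self.n_samples}), got {tuple(x.shape)}")
        if x.data.dtype != np.float32 and not x.requires_grad:
            x = nn.Tensor(x.data.astype(np.float32))
        branches = [nn.temporal_conv(x, w) for w in self.branch_weights]
        h = nn.concat(branches, axis=1)              # (N, M1, C, T)
        if self.use_attention:
            h = self.se(h)
        h = nn.spatial_collapse_conv(h, self.spatial)  # (N, M2, T)
        h = self.bn1(h).elu()
        h = nn.avg_pool_time(h, self.config.pool1)
        h = self.drop1(h)
        h = nn.depthwise_time_conv(h, self.dw_time)
        if self.use_attention:
            h = self.eca(h)
        h = self.bn2(h).elu()
        h = nn.avg_pool_time(h, self.config.pool2)
        h = self.drop2(h)
        n = h.shape[0]
        h = h.reshape(n, self.flat_dim)
        return self.bn3(self.head(h))


def build_encoder(config: EncoderConfig, n_channels: int, n_samples: int,
                  seed: int, sfreq: float = 250.0) -> Encoder:
    """Construct an encoder with deterministic initialization given ``seed``."""
    return Encoder(config, n_channels, n_samples, sfreq, seed)


def encode(encoder: Encoder, epochs: EpochSet, training_mode: bool,
           chunk: int = 512) -> FeatureBatch:
    """Encode an EpochSet to features (rows in trial order).

    Training mode uses batch statistics in every batch norm (the whole
    input is one batch); eval mode uses running statistics and processes
    the input in chunks.
    """
    encoder.train(training_mode)
    with nn.no_grad():
        if training_mode:
            feats = encoder.forward(nn.Tensor(epochs.data)).data
        else:
            parts = [encoder.forward(nn.Tensor(epochs.data[i:i + chunk])).data
                     for i in range(0, epochs.n_trials, chunk)]
            feats = np.concatenate(parts, axis=0)
    return FeatureBatch(features=feats, labels=epochs.labels.copy(),
                        subject_ids=[epochs.subject_id] * epochs.n_trials)
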