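"""Shared fixtures: small synthetic cohorts and a tiny encoder/model."""

import numpy as np
import pytest

from protoerp.data_io import EpochSet, SubjectCollection
from protoerp.encoder import EncoderConfig, build_encoder
from protoerp.protonet import AttentionProtoNet
from protoerp.simulate import SimConfig, make_cohort


# a deliberately small encoder so forward/backward passes take milliseconds
TINY_ENC = dict(temporal_kernels_s=[0.06, 0.03], filters_per_branch=2,
                pool1=2, pool2=2, dropout=0.0)


@pytest.fixture
def tiny_encoder_config():
    return EncoderConfig(**TINY_ENC)


@pytest.fixture
def tiny_cohort():
    """4 subjects x 60 trials, 4 channels, 0.4 s at 100 Hz, easy SNR."""
    cfg = SimConfig(n_subjects=4, trials_per_subject=60, n_channels=4,
                    sfreq=100.0, window_s=0.4, target_ratio=0.2,
                    erp_latency_mean_s=0.2, erp_latency_subject_sd_s=0.01,
                    erp_latency_trial_sd_s=0.01, erp_width_s=0.05,
                    ar_coeff=0.5, erp_amplitude_mean=8.0,
                    erp_amplitude_subject_sd=0.5, noise_sd=4.0, seed=11)
    return make_cohort(cfg)


@pytest.fixture
def tiny_model(tiny_cohort, tiny_encoder_config):
    enc = build_encoder(tiny_encoder_config, tiny_cohort.n_channels,
                        tiny_cohort.n_samples, seed=5, sfreq=tiny_cohort.sfreq)
    return AttentionProtoNet(enc, seed=5)


def random_epochs(rng, n_trials=20, n_channels=4, n_samples=40, sfreq=100.0,
                  subject_id="S00", n_targets=4) -> EpochSet:
    labels = np.zeros(n_trials, dtype=np.int64)
    labels[rng.choice(n_trials, n_targets, replace=False)] = 1
    return EpochSet(data=rng.standard_normal((n_trials, n_channels, n_samples)),
                    labels=labels, subject_id=subject_id, sfreq=sfreq,
                    channel_names=[f"CH{c:02d}" for c in range(n_channels)])


@pytest.fixture
def random_collection():
    rng = np.random.default_rng(3)
    return SubjectCollection({
        f"S{i:02d}": random_epochs(rng, subject_id=f"S{i:02d}")
        for i in range(3)})
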