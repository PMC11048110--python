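"""Model checkpoints: weights plus embedded configuration in one .npz file."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .encoder import EncoderConfig, build_encoder
from .protonet import AttentionProtoNet

__all__ = ["save_checkpoint", "load_checkpoint"]


def save_checkpoint(model: AttentionProtoNet, path) -> None:
    meta = {
        "encoder_config": dataclasses.asdict(model.encoder.config),
        "n_channels": model.encoder.n_channels,
        "n_samples": model.encoder.n_samples,
        "sfreq": model.encoder.sfreq,
        "seed": model.encoder.seed,
        "feature_attention": model.use_feature_attention,
        "subject_attention": model.use_subject_attention,
    }
    state = {k.replace(":", "__"): v for k, v in model.state_dict().items()}
    np.savez(Path(path), __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> AttentionProtoNet:
    with np.load(Path(path)) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        state = {k.replace("__", ":", 1): archive[k]
                 for k in archive.files if k != "__meta__"}
    encoder = build_encoder(EncoderConfig(**meta["encoder_config"]),
                            meta["n_channels"], meta["n_samples"],
                            seed=meta["seed"], sfreq=meta["sfreq"])
    model = AttentionProtoNet(encoder,
                              feature_attention=meta["feature_attention"],
                              subject_attention=meta["subject_attention"],
                              seed=meta["seed"])
    model.load_state_dict(state)
    return model
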