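"""Experiment configuration: YAML parsing, ablation patterns, snapshots."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .data_io import ValidationError
from .encoder import EncoderConfig
from .preprocess import PreprocConfig
from .simulate import SimConfig
from .train import TrainConfig

__all__ = ["ABLATION_PATTERNS", "AblationFlags", "ExperimentConfig",
           "load_experiment", "resolve_pattern"]


@dataclass
class AblationFlags:
    encoder_variant: str = "incepa"     # "incepa" | "plain"
    feature_attention: bool = True
    subject_attention: bool = True


# Network patterns for the ablation study: from the plain prototype
# network (A) through the full hybrid-attention model (E).
ABLATION_PATTERNS: dict[str, AblationFlags] = {
    "A": AblationFlags("plain", False, False),
    "B": AblationFlags("incepa", False, False),
    "C": AblationFlags("incepa", True, False),
    "D": AblationFlags("incepa", False, True),
    "E": AblationFlags("incepa", True, True),
}


def resolve_pattern(pattern: str) -> AblationFlags:
    try:
        return ABLATION_PATTERNS[pattern.upper()]
    except KeyError:
        raise ValidationError(
            f"unknown ablation pattern {pattern!r}; expected one of "
            f"{sorted(ABLATION_PATTERNS)}") from None


@dataclass
class ExperimentConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    preprocess: PreprocConfig = field(default_factory=PreprocConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    ablation: AblationFlags = field(default_factory=AblationFlags)
    output_dir: str = "protoerp_out"
    seed: int = 0

    def resolved(self) -> dict:
        return dataclasses.asdict(self)

    def snapshot(self, out_dir: Path) -> None:
        out_dir.mkdir(parents=True, exist_ok=True)
        payload = self.resolved()
        payload["root_seed"] = self.seed
        (out_dir / "config_snapshot.json").write_text(
            json.dumps(payload, indent=2, default=str))


def _build(cls, mapping: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - valid
    if unknown:
        raise ValidationError(
            f"unknown key(s) {sorted(unknown)} in section {section!r}")
    kwargs = dict(mapping)
    # YAML gives lists for tuple-valued fields
    if "window" in kwargs and kwargs["window"] is not None:
        kwargs["window"] = tuple(kwargs["window"])
    return cls(**kwargs)


def load_experiment(path) -> ExperimentConfig:
    """Parse a YAML experiment file into a fully resolved config."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = ExperimentConfig()
    if "sim" in raw:
        cfg.sim = _build(SimConfig, raw["sim"], "sim")
    if "preprocess" in raw:
        cfg.preprocess = _build(PreprocConfig, raw["preprocess"], "preprocess")
    if "encoder" in raw:
        cfg.encoder = _build(EncoderConfig, raw["encoder"], "encoder")
    if "train" in raw:
        cfg.train = _build(TrainConfig, raw["train"], "train")
    if "ablation" in raw:
        ab = raw["ablation"]
        if isinstance(ab, str):
            cfg.ablation = resolve_pattern(ab)
        else:
            cfg.ablation = _build(AblationFlags, ab, "ablation")
    cfg.output_dir = raw.get("output_dir", cfg.output_dir)
    cfg.seed = int(raw.get("seed", cfg.seed))
    # one root seed governs simulator and trainer unless overridden
    if "sim" not in raw or "seed" not in raw.get("sim", {}):
        cfg.sim.seed = cfg.seed
    if "train" not in raw or "seed" not in raw.get("train", {}):
        cfg.train.seed = cfg.seed
    cfg.encoder.variant = cfg.ablation.encoder_variant
    return cfg
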