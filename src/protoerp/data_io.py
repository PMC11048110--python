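"""Epoched multi-subject EEG containers and HDF5 persistence.

An :class:`EpochSet` holds one subject's stimulus-locked epochs as a
``(n_trials, n_channels, n_samples)`` array in microvolts with binary
labels (1 = target, 0 = nontarget).  A :class:`SubjectCollection` is an
ordered map of subjects sharing sampling rate and montage.  Collections are
persisted as a single HDF5 file with one group per subject:

    /<subject_id>/data     float32 (trials, channels, samples)
    /<subject_id>/labels   int8
    attrs: sfreq, channel_names, subject_id

plus an optional JSON manifest sidecar for human inspection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = ["EpochSet", "SubjectCollection", "save_collection", "load_collection",
           "ValidationError", "FormatError"]


class ValidationError(ValueError):
    """Raised when a container violates its invariants."""


class FormatError(ValueError):
    """Raised when a file does not follow the container layout."""


@dataclass
class EpochSet:
    """One subject's epoched EEG."""

    data: np.ndarray          # (n_trials, n_channels, n_samples), microvolts
    labels: np.ndarray        # (n_trials,), values in {0, 1}
    subject_id: str
    sfreq: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.labels = np.asarray(self.labels)
        self.validate()

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValidationError(
                f"data must be 3-D (trials, channels, samples), got {self.data.ndim}-D")
        if len(self.labels) != self.data.shape[0]:
            raise ValidationError(
                f"labels length {len(self.labels)} != n_trials {self.data.shape[0]}")
        if not np.isin(self.labels, (0, 1)).all():
            bad = np.setdiff1d(np.unique(self.labels), [0, 1])
            raise ValidationError(f"labels must be binary; found {bad.tolist()}")
        if not (self.sfreq > 0):
            raise ValidationError(f"sfreq must be positive, got {self.sfreq}")
        if not np.isfinite(self.data).all():
            raise ValidationError("data contains non-finite values")
        if self.channel_names and len(self.channel_names) != self.n_channels:
            raise ValidationError(
                f"channel_names length {len(self.channel_names)} != "
                f"n_channels {self.n_channels}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def replace_data(self, data: np.ndarray, sfreq: float | None = None) -> "EpochSet":
        """Return a copy with new signal data (labels and ids preserved)."""
        return EpochSet(data=data, labels=self.labels.copy(),
                        subject_id=self.subject_id,
                        sfreq=self.sfreq if sfreq is None else sfreq,
                        channel_names=list(self.channel_names))


@dataclass
class SubjectCollection:
    """Ordered map of subjects sharing sfreq, channel count and epoch length."""

    subjects: dict[str, EpochSet]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.subjects:
            raise ValidationError("collection must contain at least one subject")
        ref = next(iter(self.subjects.values()))
        for sid, es in self.subjects.items():
            if sid != es.subject_id:
                raise ValidationError(
                    f"key {sid!r} disagrees with subject_id {es.subject_id!r}")
            if es.sfreq != ref.sfreq:
                raise ValidationError(
                    f"sfreq mismatch for {sid}: {es.sfreq} != {ref.sfreq}")
            if es.n_channels != ref.n_channels:
                raise ValidationError(
                    f"n_channels mismatch for {sid}: "
                    f"{es.n_channels} != {ref.n_channels}")
            if es.n_samples != ref.n_samples:
                raise ValidationError(
                    f"n_samples mismatch for {sid}: "
                    f"{es.n_samples} != {ref.n_samples}")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subjects)

    @property
    def sfreq(self) -> float:
        return next(iter(self.subjects.values())).sfreq

    @property
    def n_channels(self) -> int:
        return next(iter(self.subjects.values())).n_channels

    @property
    def n_samples(self) -> int:
        return next(iter(self.subjects.values())).n_samples

    def __len__(self) -> int:
        return len(self.subjects)

    def __getitem__(self, sid: str) -> EpochSet:
        return self.subjects[sid]

    def subset(self, subject_ids) -> "SubjectCollection":
        return SubjectCollection({sid: self.subjects[sid] for sid in subject_ids})

    def map_data(self, fn) -> "SubjectCollection":
        """Apply ``fn(EpochSet) -> EpochSet`` to every subject."""
        return SubjectCollection({sid: fn(es) for sid, es in self.subjects.items()})


def save_collection(coll: SubjectCollection, path, manifest: bool = False) -> None:
    """Write a collection to a single HDF5 file (float32 data, int8 labels).

    With ``manifest=True`` a JSON sidecar ``<path>.manifest.json`` listing
    subject ids and trial counts is written alongside.
    """
    coll.validate()
    path = Path(path)
    with h5py.File(path, "w") as f:
        for sid, es in coll.subjects.items():
            grp = f.create_group(sid)
            grp.create_dataset("data", data=es.data.astype(np.float32))
            grp.create_dataset("labels", data=es.labels.astype(np.int8))
            grp.attrs["sfreq"] = float(es.sfreq)
            grp.attrs["subject_id"] = es.subject_id
            grp.attrs["channel_names"] = [str(c) for c in es.channel_names]
    if manifest:
        info = [{"subject_id": sid, "n_trials": es.n_trials,
                 "n_targets": int(es.labels.sum())}
                for sid, es in coll.subjects.items()]
        Path(str(path) + ".manifest.json").write_text(json.dumps(info, indent=2))


def load_collection(path) -> SubjectCollection:
    """Load a collection; subjects are ordered lexicographically by id."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    subjects: dict[str, EpochSet] = {}
    with h5py.File(path, "r") as f:
        for sid in sorted(f.keys()):
            grp = f[sid]
            for req in ("data", "labels"):
                if req not in grp:
                    raise FormatError(f"subject {sid!r} is missing dataset {req!r}")
            for req in ("sfreq", "subject_id"):
                if req not in grp.attrs:
                    raise FormatError(f"subject {sid!r} is missing attribute {req!r}")
            subjects[sid] = EpochSet(
                data=np.asarray(grp["data"], dtype=np.float64),
                labels=np.asarray(grp["labels"], dtype=np.int64),
                subject_id=str(grp.attrs["subject_id"]),
                sfreq=float(grp.attrs["sfreq"]),
                channel_names=[str(c) for c in grp.attrs.get("channel_names", [])],
            )
    return SubjectCollection(subjects)
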