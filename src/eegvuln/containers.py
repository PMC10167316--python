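"""Core data containers and their on-disk formats.

A *recording* is a channels x samples matrix in microvolts plus structured
metadata (subject, group, sampling rate, channel names and roles).  On disk
it is a directory holding ``metadata.yaml`` and a data matrix in either
binary (``data.npy``) or delimited-text (``data.tsv``) dialect; both are
read and written.  Epoch sets add a trial axis and per-trial metadata.
Event tables and questionnaire tables are plain TSV.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TrialEvent",
    "Recording",
    "EpochSet",
    "RejectionReport",
    "save_recording",
    "load_recording",
    "save_epochs",
    "load_epochs",
    "write_events",
    "read_events",
]

# Stimulus timing of a sustained-attention (SART) trial, milliseconds.
WORD_MS = 320
MASK_MS = 880
ISI_MS = 3020
CROSS_CHOICES_MS = (1480, 1640, 1800, 1960, 2020)

StickinessClass = Literal["less_sticky", "more_sticky", "excluded", "unlabeled"]


def classify_stickiness(rating: Optional[int]) -> StickinessClass:
    """Map a 1-9 probe rating to its class (1-4 less sticky, 6-9 more, 5 excluded)."""
    if rating is None:
        return "unlabeled"
    if not 1 <= rating <= 9:
        raise ValueError(f"stickiness rating must be in 1..9, got {rating}")
    if rating <= 4:
        return "less_sticky"
    if rating >= 6:
        return "more_sticky"
    return "excluded"


@dataclass(frozen=True)
class TrialEvent:
    """A single SART trial: stimulus onset, go/no-go type and probe labelling."""

    onset_s: float
    trial_type: Literal["go", "nogo"]
    block: int
    cross_duration_ms: int
    stickiness_rating: Optional[int] = None

    def __post_init__(self) -> None:
        if self.trial_type not in ("go", "nogo"):
            raise ValueError(f"bad trial_type {self.trial_type!r}")
        if self.stickiness_rating is not None:
            classify_stickiness(self.stickiness_rating)

    @property
    def stickiness_class(self) -> StickinessClass:
        return classify_stickiness(self.stickiness_rating)


@dataclass
class Recording:
    """Continuous multichannel EEG in microvolts."""

    data: np.ndarray  # (n_channels, n_samples), uV
    fs: float
    channel_names: tuple[str, ...]
    channel_roles: tuple[str, ...]  # 'scalp' | 'eog'
    subject_id: str = "S00"
    group: Optional[str] = None  # 'high' | 'low'

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("recording data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.channel_names = tuple(self.channel_names)
        self.channel_roles = tuple(self.channel_roles)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match data rows")
        if len(self.channel_roles) != len(self.channel_names):
            raise ValueError("channel_roles length must match channel_names")
        for r in self.channel_roles:
            if r not in ("scalp", "eog"):
                raise ValueError(f"bad channel role {r!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def scalp_indices(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.channel_roles) if r == "scalp"])

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None

    def copy(self) -> "Recording":
        return dataclasses.replace(self, data=self.data.copy())


@dataclass
class EpochSet:
    """Stimulus-locked trials: a trials x channels x time tensor in microvolts.

    ``info`` holds one row per trial (onset_s, trial_type, block,
    stickiness_rating, stickiness_class, kept).  ``tmin_s`` is the time of
    the first sample relative to stimulus onset.
    """

    data: np.ndarray  # (n_trials, n_channels, n_times), uV
    tmin_s: float
    fs: float
    channel_names: tuple[str, ...]
    channel_roles: tuple[str, ...]
    info: pd.DataFrame = field(default_factory=pd.DataFrame)
    subject_id: str = "S00"
    group: Optional[str] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (trials x channels x time)")
        self.channel_names = tuple(self.channel_names)
        self.channel_roles = tuple(self.channel_roles)
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must match data channel axis")
        if self.info.empty and self.data.shape[0] > 0:
            self.info = pd.DataFrame({"kept": np.ones(self.data.shape[0], dtype=bool)})
        if len(self.info) != self.data.shape[0]:
            raise ValueError("info rows must match trial count")
        if "kept" not in self.info.columns:
            self.info = self.info.assign(kept=True)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def tmax_s(self) -> float:
        return self.tmin_s + self.n_times / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.tmin_s + np.arange(self.n_times) / self.fs

    @property
    def scalp_indices(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.channel_roles) if r == "scalp"])

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None

    def copy(self) -> "EpochSet":
        return dataclasses.replace(self, data=self.data.copy(), info=self.info.copy())


@dataclass(frozen=True)
class RejectionReport:
    """Outcome of automatic artifact rejection."""

    n_total: int
    n_rejected: int
    reasons: tuple[str, ...]  # per trial: '' if kept, else reason code

    @property
    def proportion_rejected(self) -> float:
        return self.n_rejected / self.n_total if self.n_total else 0.0

    def to_text(self) -> str:
        lines = [
            f"n_total\t{self.n_total}",
            f"n_rejected\t{self.n_rejected}",
            f"proportion_rejected\t{self.proportion_rejected:.6f}",
        ]
        lines += [f"trial_{i}\t{r or 'kept'}" for i, r in enumerate(self.reasons)]
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Recording / epoch containers on disk
# ---------------------------------------------------------------------------


def _write_matrix(path_stem: Path, arr: np.ndarray, fmt: str) -> str:
    if fmt == "npy":
        fname = path_stem.with_suffix(".npy")
        np.save(fname, arr)
    elif fmt == "tsv":
        fname = path_stem.with_suffix(".tsv")
        flat = arr.reshape(-1, arr.shape[-1]) if arr.ndim == 3 else arr
        np.savetxt(fname, flat, delimiter="\t", fmt="%.10g")
    else:
        raise ValueError(f"unknown data format {fmt!r} (use 'npy' or 'tsv')")
    return fname.name


def _read_matrix(folder: Path, fname: str, shape: Sequence[int]) -> np.ndarray:
    path = folder / fname
    if path.suffix == ".npy":
        arr = np.load(path)
    else:
        arr = np.loadtxt(path, delimiter="\t", ndmin=2)
    return arr.reshape(tuple(shape))


def save_recording(rec: Recording, folder: str | Path, fmt: str = "npy") -> Path:
    """Write a recording container (metadata.yaml + data matrix) to *folder*."""
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    fname = _write_matrix(folder / "data", rec.data, fmt)
    meta = {
        "kind": "recording",
        "subject_id": rec.subject_id,
        "group": rec.group,
        "fs": float(rec.fs),
        "channel_names": list(rec.channel_names),
        "channel_roles": list(rec.channel_roles),
        "shape": list(rec.data.shape),
        "data_file": fname,
        "units": "uV",
    }
    (folder / "metadata.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    return folder


def load_recording(folder: str | Path) -> Recording:
    folder = Path(folder)
    meta = yaml.safe_load((folder / "metadata.yaml").read_text())
    if meta.get("kind") != "recording":
        raise ValueError(f"{folder} is not a recording container")
    data = _read_matrix(folder, meta["data_file"], meta["shape"])
    return Recording(
        data=data,
        fs=meta["fs"],
        channel_names=tuple(meta["channel_names"]),
        channel_roles=tuple(meta["channel_roles"]),
        subject_id=meta["subject_id"],
        group=meta.get("group"),
    )


def save_epochs(ep: EpochSet, folder: str | Path, fmt: str = "npy") -> Path:
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    fname = _write_matrix(folder / "data", ep.data, fmt)
    meta = {
        "kind": "epochs",
        "subject_id": ep.subject_id,
        "group": ep.group,
        "fs": float(ep.fs),
        "tmin_s": float(ep.tmin_s),
        "channel_names": list(ep.channel_names),
        "channel_roles": list(ep.channel_roles),
        "shape": list(ep.data.shape),
        "data_file": fname,
        "units": "uV",
    }
    (folder / "metadata.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    ep.info.to_csv(folder / "trials.tsv", sep="\t", index=False)
    return folder


def load_epochs(folder: str | Path) -> EpochSet:
    folder = Path(folder)
    meta = yaml.safe_load((folder / "metadata.yaml").read_text())
    if meta.get("kind") != "epochs":
        raise ValueError(f"{folder} is not an epochs container")
    data = _read_matrix(folder, meta["data_file"], meta["shape"])
    info = pd.read_csv(folder / "trials.tsv", sep="\t")
    return EpochSet(
        data=data,
        tmin_s=meta["tmin_s"],
        fs=meta["fs"],
        channel_names=tuple(meta["channel_names"]),
        channel_roles=tuple(meta["channel_roles"]),
        info=info,
        subject_id=meta["subject_id"],
        group=meta.get("group"),
    )


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------


def events_to_frame(events: Sequence[TrialEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "onset_s": [e.onset_s for e in events],
            "trial_type": [e.trial_type for e in events],
            "block": [e.block for e in events],
            "cross_duration_ms": [e.cross_duration_ms for e in events],
            "stickiness_rating": [e.stickiness_rating for e in events],
            "stickiness_class": [e.stickiness_class for e in events],
        }
    )


def write_events(events: Sequence[TrialEvent], path: str | Path) -> Path:
    path = Path(path)
    events_to_frame(events).to_csv(path, sep="\t", index=False)
    return path


def read_events(path: str | Path) -> list[TrialEvent]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        rating = row.stickiness_rating
        rating = None if pd.isna(rating) else int(rating)
        out.append(
            TrialEvent(
                onset_s=float(row.onset_s),
                trial_type=row.trial_type,
                block=int(row.block),
                cross_duration_ms=int(row.cross_duration_ms),
                stickiness_rating=rating,
            )
        )
    return out
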