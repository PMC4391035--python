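"""Domain containers, configuration, and file I/O for the grasp-decoding pipeline.

The central object is :class:`Recording`: synchronized multichannel EEG
(microvolts) and 15 hand joint angles (degrees) sampled at a common rate,
plus movement onset/offset events labelled with the grasped object. All
downstream stages (preprocessing, synergy extraction, Wiener decoding,
surrogate nulls, grasp classification) consume and produce these containers.

Supported on-disk formats
-------------------------
* ``container`` — a versioned NumPy ``.npz`` archive holding signals, labels,
  events and a config snapshot (lossless round trip).
* ``csv`` — delimited text, one column per channel with a header row of
  labels; kinematics and events in companion tables.
* ``brainvision`` / ``edf`` — vendor formats, read through :mod:`mne`.
  BrainVision marker semantics are never guessed: the caller supplies a
  marker description → (role, object label) mapping.

Sample indexing is 0-based and intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTAINER_VERSION = "graspdecode-container-v1"

#: The five grasped objects, each requiring a distinct grasp type.
OBJECTS: tuple[str, ...] = ("can", "card", "cd", "penny", "screwdriver")

#: The 15 hand joints retained for analysis: MCP and PIP of the four
#: fingers, thumb CMC/MCP/IP, and the four abduction joints.
JOINT_LABELS: tuple[str, ...] = (
    "index_MCP", "middle_MCP", "ring_MCP", "little_MCP",
    "index_PIP", "middle_PIP", "ring_PIP", "little_PIP",
    "thumb_CMC", "thumb_MCP", "thumb_IP",
    "ABD_thumb_index", "ABD_index_middle", "ABD_middle_ring", "ABD_ring_little",
)

#: Default 64-channel 10-20 montage (extended layout with mastoids).
DEFAULT_MONTAGE_64: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
    "AF7", "AF3", "AF4", "AF8",
    "F5", "F1", "F2", "F6",
    "M1", "FT7", "FC3", "FC4", "FT8", "M2",
    "C5", "C1", "C2", "C6",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P5", "P1", "P2", "P6",
    "PO7", "PO3", "POz", "PO4", "PO8",
)

#: Peripheral channels excluded from analysis (prone to muscular artifact).
EXCLUDED_CHANNELS: tuple[str, ...] = ("M1", "M2", "TP9", "TP10", "PO9", "PO10")

#: Frontal channels most affected by ocular artifact (omission control).
FRONTAL_CHANNELS: tuple[str, ...] = ("Fp1", "Fp2", "AF7", "AF8")


class AlignmentError(ValueError):
    """EEG and kinematics disagree on sample count / rate, or labels clash."""


class ConfigError(ValueError):
    """A configuration document is malformed or holds an out-of-range value."""


@dataclass(frozen=True)
class TrialEvent:
    """One reach-to-grasp trial: movement onset/offset plus the object label.

    Onset and offset are 0-based sample indices into the recording;
    ``onset_sample < offset_sample`` and both must lie inside the recording.
    """

    onset_sample: int
    offset_sample: int
    object_label: str

    def __post_init__(self) -> None:
        if not (0 <= self.onset_sample < self.offset_sample):
            raise ValueError(
                f"require 0 <= onset < offset, got "
                f"({self.onset_sample}, {self.offset_sample})"
            )


@dataclass
class Recording:
    """Synchronized EEG and hand kinematics with trial events.

    Parameters
    ----------
    eeg : ndarray, shape (n_channels, n_samples)
        EEG in microvolts (or derived units after preprocessing).
    fs : float
        Sampling rate in Hz, shared by EEG and kinematics.
    channel_labels : sequence of str
        Unique 10-20 channel names, one per EEG row.
    kin : ndarray, shape (15, n_samples), optional
        Joint angles in degrees (or deg/s after differentiation).
    joint_labels : sequence of str, optional
        Names of the 15 joints; defaults to :data:`JOINT_LABELS`.
    events : list of TrialEvent
    """

    eeg: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    kin: np.ndarray | None = None
    joint_labels: tuple[str, ...] | None = None
    events: list[TrialEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        if self.eeg.ndim != 2:
            raise ValueError("eeg must be a 2-D (channels x samples) array")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.eeg.shape[0]:
            raise AlignmentError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.eeg.shape[0]} EEG rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise AlignmentError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.kin is not None:
            self.kin = np.asarray(self.kin, dtype=float)
            if self.joint_labels is None:
                self.joint_labels = JOINT_LABELS
            self.joint_labels = tuple(self.joint_labels)
            if len(self.joint_labels) != 15:
                raise AlignmentError(
                    f"expected exactly 15 joint labels, got {len(self.joint_labels)}"
                )
            if self.kin.shape != (15, self.eeg.shape[1]):
                raise AlignmentError(
                    f"kinematics shape {self.kin.shape} does not align with "
                    f"EEG ({self.eeg.shape[0]} x {self.eeg.shape[1]}); "
                    "expected (15, n_samples)"
                )
        for ev in self.events:
            if ev.offset_sample >= self.n_samples:
                raise ValueError(
                    f"event {ev} extends past recording end ({self.n_samples})"
                )

    # -- convenience ------------------------------------------------------

    @property
    def n_channels(self) -> int:
        return self.eeg.shape[0]

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def replace(self, **kwargs) -> "Recording":
        """Return a shallow copy with the given fields swapped out."""
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All tunable parameters of the analysis chain.

    Defaults reproduce the published settings: 0.3-1 Hz zero-phase 4th-order
    Butterworth band, downsampling to 100 Hz, 11 lags (0-100 ms in 10 ms
    steps), trial margins of 400 ms pre-onset / 100 ms post-offset, six
    peripheral channels excluded, 3 retained synergies, 8-fold CV, RBF widths
    {5, 10, 15} over 8 scalp regions, and 5 surrogate repetitions.
    """

    band: tuple[float, float] = (0.3, 1.0)
    filter_order: int = 4
    target_fs: float = 100.0
    max_lag: int = 10               # L, in samples at target_fs (10 -> 100 ms)
    lag_step: int = 1               # lag spacing in samples at target_fs
    pre_ms: float = 400.0           # trial margin before movement onset
    post_ms: float = 100.0          # trial margin after movement offset
    excluded_channels: tuple[str, ...] = EXCLUDED_CHANNELS
    n_synergies: int = 3
    cv_folds: int = 8
    seed: int = 0
    roi_map: dict[str, tuple[str, ...]] | None = None  # None -> default map
    sigmas: tuple[float, ...] = (5.0, 10.0, 15.0)
    svm_cost: float = 1.0
    surrogate_reps: int = 5
    fold_safe: bool = True          # leakage-free standardization/PCA per fold
    frontal_channels: tuple[str, ...] = FRONTAL_CHANNELS

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (0 < lo < hi):
            raise ConfigError(f"band edges must satisfy 0 < low < high, got {self.band}")
        for name in ("filter_order", "target_fs", "max_lag", "cv_folds",
                     "n_synergies", "svm_cost", "surrogate_reps", "lag_step"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.pre_ms < 0 or self.post_ms < 0:
            raise ConfigError("trial margins must be non-negative")
        if any(s <= 0 for s in self.sigmas):
            raise ConfigError("kernel widths must be positive")
        if hi >= self.target_fs / 2:
            raise ConfigError("band upper edge must lie below target Nyquist")
        # Lag history must fit inside the pre-onset margin so no trial ever
        # touches samples without full lag context.
        if self.max_lag * self.lag_step / self.target_fs * 1000.0 > self.pre_ms:
            raise ConfigError("pre-onset margin shorter than the lag history")

    @classmethod
    def from_dict(cls, doc: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(doc)
        for key in ("band", "excluded_channels", "sigmas", "frontal_channels"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        if kwargs.get("roi_map") is not None:
            kwargs["roi_map"] = {k: tuple(v) for k, v in kwargs["roi_map"].items()}
        return cls(**kwargs)

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["band"] = list(doc["band"])
        return doc


def load_config(path: str | Path) -> PipelineConfig:
    """Read a JSON config; unspecified keys take the published defaults.

    The resolved configuration is echoed to the log so a run can be
    reproduced bit-for-bit.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"malformed config {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a JSON object")
    cfg = PipelineConfig.from_dict(doc)
    logger.info("resolved config: %s", json.dumps(cfg.to_dict(), sort_keys=True))
    return cfg


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _events_to_array(events: Sequence[TrialEvent]) -> np.ndarray:
    return np.array(
        [(ev.onset_sample, ev.offset_sample, ev.object_label) for ev in events],
        dtype=object,
    ).reshape(len(events), 3)


def _events_from_array(arr: np.ndarray) -> list[TrialEvent]:
    return [TrialEvent(int(a), int(b), str(lab)) for a, b, lab in arr]


def write_recording(rec: Recording, path: str | Path, fmt: str = "container") -> Path:
    """Persist a recording as the internal container or delimited text.

    ``container`` writes a single ``.npz`` archive. ``csv`` writes the EEG
    table at *path* plus ``<stem>_kin.csv`` / ``<stem>_events.csv``
    companions when kinematics or events are present.
    """
    path = Path(path)
    if fmt == "container":
        payload: dict[str, np.ndarray] = {
            "version": np.array(CONTAINER_VERSION),
            "eeg": rec.eeg,
            "fs": np.array(rec.fs),
            "channel_labels": np.array(rec.channel_labels),
        }
        if rec.kin is not None:
            payload["kin"] = rec.kin
            payload["joint_labels"] = np.array(rec.joint_labels)
        if rec.events:
            ev = _events_to_array(rec.events)
            payload["event_onsets"] = ev[:, 0].astype(np.int64)
            payload["event_offsets"] = ev[:, 1].astype(np.int64)
            payload["event_labels"] = ev[:, 2].astype(str)
        np.savez_compressed(path, **payload)
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    if fmt == "csv":
        pd.DataFrame(rec.eeg.T, columns=list(rec.channel_labels)).to_csv(
            path, index=False, float_format="%.12g"
        )
        if rec.kin is not None:
            pd.DataFrame(rec.kin.T, columns=list(rec.joint_labels)).to_csv(
                path.with_name(path.stem + "_kin.csv"), index=False,
                float_format="%.12g",
            )
        if rec.events:
            pd.DataFrame(
                [(e.onset_sample, e.offset_sample, e.object_label) for e in rec.events],
                columns=["onset_sample", "offset_sample", "object_label"],
            ).to_csv(path.with_name(path.stem + "_events.csv"), index=False)
        return path
    raise ValueError(f"unknown format {fmt!r}")


def _read_container(path: Path) -> Recording:
    with np.load(path, allow_pickle=False) as npz:
        version = str(npz["version"])
        if version != CONTAINER_VERSION:
            raise ValueError(f"unsupported container version {version!r}")
        events = []
        if "event_onsets" in npz:
            events = [
                TrialEvent(int(a), int(b), str(lab))
                for a, b, lab in zip(
                    npz["event_onsets"], npz["event_offsets"], npz["event_labels"]
                )
            ]
        return Recording(
            eeg=npz["eeg"],
            fs=float(npz["fs"]),
            channel_labels=tuple(str(c) for c in npz["channel_labels"]),
            kin=npz["kin"] if "kin" in npz else None,
            joint_labels=tuple(str(j) for j in npz["joint_labels"])
            if "joint_labels" in npz else None,
            events=events,
        )


def _read_csv(path: Path, fs: float | None, kin_path, events_path) -> Recording:
    if fs is None:
        raise ValueError("csv format carries no sampling rate; pass fs=")
    df = pd.read_csv(path)
    eeg = df.to_numpy(dtype=float).T
    kin = None
    joint_labels = None
    if kin_path is not None:
        kdf = pd.read_csv(kin_path)
        kin = kdf.to_numpy(dtype=float).T
        joint_labels = tuple(kdf.columns)
        if kin.shape[1] != eeg.shape[1]:
            raise AlignmentError(
                f"EEG has {eeg.shape[1]} samples but kinematics has {kin.shape[1]}"
            )
    events = []
    if events_path is not None:
        edf = pd.read_csv(events_path)
        events = [
            TrialEvent(int(r.onset_sample), int(r.offset_sample), str(r.object_label))
            for r in edf.itertuples()
        ]
    return Recording(eeg=eeg, fs=fs, channel_labels=tuple(df.columns),
                     kin=kin, joint_labels=joint_labels, events=events)


def _events_from_annotations(raw, fs: float,
                             marker_map: Mapping[str, tuple[str, str]] | None,
                             ) -> list[TrialEvent]:
    """Pair onset/offset annotations into TrialEvents via a user mapping.

    ``marker_map`` maps an annotation description to ``("onset", label)`` or
    ``("offset", label)``. Onsets and offsets are paired in temporal order;
    an offset closes the most recent open onset with a matching label.
    """
    if marker_map is None:
        return []
    open_onsets: list[tuple[int, str]] = []
    events: list[TrialEvent] = []
    for ann in sorted(raw.annotations, key=lambda a: a["onset"]):
        desc = ann["description"]
        if desc not in marker_map:
            continue
        role, label = marker_map[desc]
        sample = int(round(ann["onset"] * fs))
        if role == "onset":
            open_onsets.append((sample, label))
        elif role == "offset":
            if not open_onsets:
                logger.warning("offset marker %r at sample %d without onset; skipped",
                               desc, sample)
                continue
            onset_sample, onset_label = open_onsets.pop()
            events.append(TrialEvent(onset_sample, sample, onset_label or label))
        else:
            raise ValueError(f"marker role must be onset/offset, got {role!r}")
    for sample, label in open_onsets:
        logger.warning("onset marker at sample %d (%s) never closed; dropped",
                       sample, label)
    return events


def _read_mne(path: Path, fmt: str, marker_map) -> Recording:
    import mne  # deferred: mne import is heavy

    if fmt == "brainvision":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns Volts
    fs = float(raw.info["sfreq"])
    events = _events_from_annotations(raw, fs, marker_map)
    return Recording(eeg=data, fs=fs, channel_labels=tuple(raw.ch_names),
                     events=events)


def read_recording(path: str | Path, fmt: str = "container", *,
                   fs: float | None = None,
                   kin_path: str | Path | None = None,
                   events_path: str | Path | None = None,
                   marker_map: Mapping[str, tuple[str, str]] | None = None,
                   ) -> Recording:
    """Load a recording from disk.

    Parameters
    ----------
    fmt : {"container", "csv", "brainvision", "edf"}
    fs : float
        Required for ``csv`` (plain tables carry no rate).
    kin_path, events_path :
        Companion tables for ``csv`` input.
    marker_map :
        For vendor formats: annotation description ->
        ``("onset"|"offset", object_label)``; vendor marker semantics are
        never guessed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "container":
        return _read_container(path)
    if fmt == "csv":
        return _read_csv(path, fs, kin_path, events_path)
    if fmt in ("brainvision", "edf"):
        return _read_mne(path, fmt, marker_map)
    raise ValueError(f"unknown format {fmt!r}")
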