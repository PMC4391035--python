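"""Signal conditioning for EEG and kinematics.

The chain, in execution order (mirroring the analysis flowchart):

1. EEG: linear detrend, zero-phase 4th-order Butterworth high-pass at
   0.3 Hz, optional spatial projection (artifact-subspace removal hook),
   zero-phase 4th-order low-pass at 1 Hz.
2. Kinematics: zero-phase low-pass at 1 Hz, with the distortion quantified
   by the signal-to-error ratio SER = 10 log10(Var(y) / MSE(y, y*)).
3. Both: downsample to 100 Hz (integer decimation — the 1 Hz low-pass is
   the anti-alias filter) and first-difference differentiation scaled by
   the sampling rate, giving uV/s and deg/s.
4. EEG: lag embedding — 11 time-shifted copies spanning 0-100 ms of
   history per channel.
5. Segmentation into trials from 400 ms before movement onset to 100 ms
   after movement offset.
6. Standardization of each (channel, lag) feature to zero mean / unit SD.

Standardization across *all* trials leaks fold statistics into held-out
data; a fold-safe variant (statistics from training trials only) is the
default for synthetic validation, with the all-trials variant available
for fidelity to the original analysis.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io_core import PipelineConfig, Recording

logger = logging.getLogger(__name__)

__all__ = [
    "LagTensor",
    "TrialSet",
    "FeatureStats",
    "bandlimit_eeg",
    "apply_spatial_projection",
    "exclude_channels",
    "filter_kinematics",
    "resample_and_differentiate",
    "compute_ser",
    "lag_embed",
    "segment_trials",
    "standardize",
    "preprocess",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class LagTensor:
    """Lag-embedded EEG: ``data[j, n, k] = eeg[n, t0 + j - k*step]``.

    ``data`` covers only samples with full lag history (absolute time index
    ``t0 + j`` with ``t0 = L*step``); earlier samples are invalid because
    they precede the available history. The lag axis has ``L + 1`` entries,
    lag 0 first.
    """

    data: np.ndarray                     # (n_valid, channels, L+1)
    t0: int                              # absolute index of data[0]
    L: int
    step: int
    fs: float
    channel_labels: tuple[str, ...]

    @property
    def step_ms(self) -> float:
        return self.step / self.fs * 1000.0

    @property
    def n_lags(self) -> int:
        return self.L + 1

    def value(self, t: int, n: int, k: int) -> float:
        """Signal of channel ``n`` at absolute time ``t - k*step``."""
        if t < self.t0:
            raise IndexError(f"sample {t} precedes available lag history ({self.t0})")
        return float(self.data[t - self.t0, n, k])


@dataclass
class FeatureStats:
    """Per-(channel, lag) standardization statistics."""

    mean: np.ndarray                     # (channels, L+1)
    sd: np.ndarray                       # (channels, L+1), zero-variance -> 1


@dataclass
class TrialSet:
    """Per-trial lag-embedded EEG paired with kinematic trajectories.

    ``eeg[i]`` is (T_i, channels, L+1), ``velocities[i]`` is (T_i, 15);
    ``pcs`` (synergy trajectories) is filled by the synergies module.
    ``start_offset`` is the first sample of each trial relative to movement
    onset (negative: the pre-onset margin), used to locate
    classification windows at a given latency.
    """

    eeg: list[np.ndarray]
    velocities: list[np.ndarray]
    labels: list[str]
    channel_labels: tuple[str, ...]
    joint_labels: tuple[str, ...]
    fs: float
    L: int
    lag_step: int
    start_offset: list[int] = field(default_factory=list)
    pcs: list[np.ndarray] | None = None
    stats: FeatureStats | None = None    # set once standardized

    def __post_init__(self) -> None:
        if len(self.eeg) != len(self.velocities) or len(self.eeg) != len(self.labels):
            raise ValueError("per-trial lists must have equal length")
        for e, v in zip(self.eeg, self.velocities):
            if e.shape[0] != v.shape[0]:
                raise ValueError("EEG and kinematics lengths differ within a trial")
        if not self.start_offset:
            self.start_offset = [0] * len(self.eeg)

    @property
    def n_trials(self) -> int:
        return len(self.eeg)

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def subset(self, indices) -> "TrialSet":
        """New TrialSet restricted to the given trial indices."""
        idx = list(indices)
        return dataclasses.replace(
            self,
            eeg=[self.eeg[i] for i in idx],
            velocities=[self.velocities[i] for i in idx],
            labels=[self.labels[i] for i in idx],
            start_offset=[self.start_offset[i] for i in idx],
            pcs=None if self.pcs is None else [self.pcs[i] for i in idx],
        )

    def select_channels(self, labels) -> "TrialSet":
        """New TrialSet restricted to the named channels (order preserved
        as given)."""
        idx = [self.channel_labels.index(ch) for ch in labels]
        return dataclasses.replace(
            self,
            eeg=[e[:, idx, :] for e in self.eeg],
            channel_labels=tuple(labels),
        )

    def stacked_eeg(self) -> np.ndarray:
        """All trials concatenated: (sum T_i, channels, L+1)."""
        return np.concatenate(self.eeg, axis=0)

    def design_matrix(self) -> np.ndarray:
        """Flattened (channel, lag) feature matrix, (sum T_i, C*(L+1))."""
        x = self.stacked_eeg()
        return x.reshape(x.shape[0], -1)

    def stacked_velocities(self) -> np.ndarray:
        return np.concatenate(self.velocities, axis=0)

    def stacked_pcs(self) -> np.ndarray:
        if self.pcs is None:
            raise ValueError("synergy trajectories not yet projected")
        return np.concatenate(self.pcs, axis=0)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _sosfiltfilt(x: np.ndarray, fs: float, cutoff, btype: str, order: int,
                 ) -> np.ndarray:
    sos = sps.butter(order, cutoff, btype=btype, fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def bandlimit_eeg(rec: Recording, band: tuple[float, float] = (0.3, 1.0),
                  order: int = 4) -> Recording:
    """Detrend and band-limit the EEG with zero-phase Butterworth filters.

    A linear trend is removed first; the high-pass and low-pass are applied
    as separate forward-backward (zero-phase) passes, so the effective
    magnitude response is the squared ``order``-th order Butterworth.
    Output length equals input length. Kinematics are untouched.
    """
    lo, hi = band
    nyq = rec.fs / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band {band} outside (0, {nyq}) or misordered")
    if rec.n_samples <= 3 * order:
        raise ValueError("signal too short for the filter order")
    x = sps.detrend(rec.eeg, axis=-1)
    x = _sosfiltfilt(x, rec.fs, lo, "highpass", order)
    x = _sosfiltfilt(x, rec.fs, hi, "lowpass", order)
    return rec.replace(eeg=x)


def apply_spatial_projection(rec: Recording, projection: np.ndarray) -> Recording:
    """Left-multiply the EEG by a channels x channels projection matrix.

    Hook for artifact-subspace removal (e.g. projecting out an
    independent-component topography); labels are unchanged. Because
    spatial mixing commutes with the per-channel temporal filters, its
    position within the filtering chain is immaterial.
    """
    projection = np.asarray(projection, dtype=float)
    if projection.ndim != 2 or projection.shape[0] != projection.shape[1]:
        raise ValueError("projection must be square")
    if projection.shape[0] != rec.n_channels:
        raise ValueError(
            f"projection is {projection.shape[0]}-dim but recording has "
            f"{rec.n_channels} channels"
        )
    return rec.replace(eeg=projection @ rec.eeg)


def exclude_channels(rec: Recording, labels) -> Recording:
    """Drop the named channels, preserving the order of the rest."""
    labels = set(labels)
    unknown = labels - set(rec.channel_labels)
    if unknown:
        raise ValueError(f"channels not in montage: {sorted(unknown)}")
    keep = [i for i, ch in enumerate(rec.channel_labels) if ch not in labels]
    return rec.replace(
        eeg=rec.eeg[keep],
        channel_labels=tuple(rec.channel_labels[i] for i in keep),
    )


def compute_ser(raw: np.ndarray, filtered: np.ndarray) -> float:
    """Signal-to-error ratio in dB: ``10 log10(Var(y) / MSE(y, y*))``.

    Gauges the distortion a filter introduced; identical signals give
    +infinity.
    """
    raw = np.asarray(raw, dtype=float)
    filtered = np.asarray(filtered, dtype=float)
    if raw.shape != filtered.shape:
        raise ValueError("raw and filtered signals must have equal length")
    var = raw.var()
    if var == 0:
        raise ValueError("zero-variance raw signal: SER undefined")
    mse = np.mean((raw - filtered) ** 2)
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(var / mse))


def filter_kinematics(rec: Recording, cutoff: float = 1.0, order: int = 4,
                      ) -> tuple[Recording, np.ndarray]:
    """Zero-phase low-pass of the joint angles; returns per-joint SER (dB)."""
    if rec.kin is None:
        raise ValueError("recording has no kinematics")
    filtered = _sosfiltfilt(rec.kin, rec.fs, cutoff, "lowpass", order)
    ser = np.array([compute_ser(r, f) for r, f in zip(rec.kin, filtered)])
    logger.info("kinematics SER after low-pass: %.1f +/- %.1f dB",
                float(np.mean(ser)), float(np.std(ser)))
    return rec.replace(kin=filtered), ser


def resample_and_differentiate(rec: Recording, target_fs: float) -> Recording:
    """Integer-factor decimation followed by scaled first differences.

    The preceding 1 Hz low-pass serves as the anti-alias filter, so
    decimation is plain subsampling. The first difference is scaled by the
    target rate to give physical units per second, and the value at t=0 is
    repeated so output length is preserved. Applied to EEG and kinematics
    alike; event sample indices are rescaled.
    """
    factor = rec.fs / target_fs
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"target_fs {target_fs} does not divide fs {rec.fs}")
    factor = int(round(factor))

    def _process(x: np.ndarray) -> np.ndarray:
        y = x[:, ::factor]
        d = np.diff(y, axis=-1) * target_fs
        return np.concatenate([d[:, :1], d], axis=-1)

    events = [
        dataclasses.replace(ev, onset_sample=ev.onset_sample // factor,
                            offset_sample=ev.offset_sample // factor)
        for ev in rec.events
    ]
    return rec.replace(
        eeg=_process(rec.eeg),
        kin=None if rec.kin is None else _process(rec.kin),
        fs=target_fs,
        events=events,
    )


# ---------------------------------------------------------------------------
# Lag embedding and segmentation
# ---------------------------------------------------------------------------

def lag_embed(rec: Recording, L: int = 10, step: int = 1) -> LagTensor:
    """Stack ``L + 1`` time-shifted copies of each channel.

    ``data[j, n, k]`` equals channel ``n`` at absolute time
    ``t0 + j - k*step`` with ``t0 = L*step``; only samples with full lag
    history are exposed. The tensor is a zero-copy strided view of the
    signal, so memory stays at one copy of the EEG.
    """
    if L < 0:
        raise ValueError("L must be non-negative")
    if step < 1:
        raise ValueError("step must be >= 1")
    span = L * step
    if span >= rec.n_samples:
        raise ValueError("lag history exceeds recording length")
    x = np.ascontiguousarray(rec.eeg.T)          # (T, C)
    if span == 0:
        data = x[:, :, None]
    else:
        # windows[j, n, :] = x[j : j + span + 1, n]; reversing and striding
        # the window axis yields lag order 0, step, ..., L*step.
        windows = np.lib.stride_tricks.sliding_window_view(x, span + 1, axis=0)
        data = windows[:, :, ::-step]
    data = data[:, :, : L + 1]
    return LagTensor(data=data, t0=span, L=L, step=step, fs=rec.fs,
                     channel_labels=rec.channel_labels)


def segment_trials(lagged: LagTensor, kin: Recording, events=None, *,
                   pre_ms: float = 400.0, post_ms: float = 100.0,
                   post_from: str = "offset") -> TrialSet:
    """Cut lag-embedded EEG and kinematics into per-trial segments.

    A trial spans ``onset - pre_ms`` up to and including
    ``offset + post_ms`` (half-open end one sample beyond); with
    ``post_from="onset"`` the end margin is measured from movement onset
    instead, which the grasp classifier uses for its -1 .. 3 s windows.
    Trials whose window (including lag history) falls outside the recording
    are rejected with a logged warning rather than silently dropped.
    """
    if events is None:
        events = kin.events
    if abs(lagged.fs - kin.fs) > 1e-9:
        raise ValueError("lagged EEG and kinematics sampling rates differ")
    fs = kin.fs
    pre = int(round(pre_ms / 1000.0 * fs))
    post = int(round(post_ms / 1000.0 * fs))
    if post_from not in ("offset", "onset"):
        raise ValueError("post_from must be 'offset' or 'onset'")

    eeg_trials, vel_trials, labels, starts = [], [], [], []
    n_valid = lagged.data.shape[0]
    for ev in events:
        start = ev.onset_sample - pre
        ref = ev.offset_sample if post_from == "offset" else ev.onset_sample
        end = ref + post + 1                       # half-open
        if start < lagged.t0 or end > lagged.t0 + n_valid or end > kin.n_samples:
            logger.warning(
                "trial at onset %d rejected: window [%d, %d) outside recording",
                ev.onset_sample, start, end)
            continue
        eeg_trials.append(np.array(lagged.data[start - lagged.t0:end - lagged.t0]))
        vel_trials.append(kin.kin[:, start:end].T.copy())
        labels.append(ev.object_label)
        starts.append(start - ev.onset_sample)
    return TrialSet(
        eeg=eeg_trials, velocities=vel_trials, labels=labels,
        channel_labels=lagged.channel_labels, joint_labels=kin.joint_labels,
        fs=fs, L=lagged.L, lag_step=lagged.step, start_offset=starts,
    )


def standardize(trials: TrialSet, stats: FeatureStats | None = None,
                ) -> tuple[TrialSet, FeatureStats]:
    """Zero-mean / unit-SD each (channel, lag) feature.

    Statistics are computed over all time points of all trials unless
    ``stats`` is supplied (fold-safe reuse of training-fold statistics on
    held-out trials). Zero-variance features are left at zero with a
    warning.
    """
    if trials.n_trials == 0:
        raise ValueError("empty TrialSet")
    if stats is None:
        x = trials.stacked_eeg()
        mean = x.mean(axis=0)
        sd = x.std(axis=0)
        # constant features leave roundoff-scale sd, not exactly zero
        dead = sd <= 100 * np.finfo(float).eps * np.maximum(1.0, np.abs(mean))
        if np.any(dead):
            logger.warning("%d zero-variance (channel, lag) features left at 0",
                           int(dead.sum()))
            sd = np.where(dead, 1.0, sd)
        stats = FeatureStats(mean=mean, sd=sd)
    out = [(e - stats.mean) / stats.sd for e in trials.eeg]
    return dataclasses.replace(trials, eeg=out, stats=stats), stats


# ---------------------------------------------------------------------------
# Composed chain
# ---------------------------------------------------------------------------

def preprocess(rec: Recording, config: PipelineConfig | None = None, *,
               projection: np.ndarray | None = None,
               pre_ms: float | None = None, post_ms: float | None = None,
               post_from: str = "offset",
               ) -> tuple[Recording, TrialSet, np.ndarray]:
    """Run the full conditioning chain on a raw recording.

    Returns ``(prelag, trials, ser)``: the continuous pre-lag-embedding
    stage (band-limited, channel-pruned, downsampled, differentiated — the
    stage at which phase-scrambled surrogates are built), the segmented
    unstandardized TrialSet, and the per-joint SER in dB. Standardization
    is left to the cross-validation driver so fold-safe statistics remain
    possible.
    """
    config = config or PipelineConfig()
    r = bandlimit_eeg(rec, config.band, config.filter_order)
    if projection is not None:
        r = apply_spatial_projection(r, projection)
    r, ser = filter_kinematics(r, cutoff=config.band[1], order=config.filter_order)
    drop = [ch for ch in config.excluded_channels if ch in r.channel_labels]
    r = exclude_channels(r, drop)
    prelag = resample_and_differentiate(r, config.target_fs)
    lagged = lag_embed(prelag, L=config.max_lag, step=config.lag_step)
    trials = segment_trials(
        lagged, prelag,
        pre_ms=config.pre_ms if pre_ms is None else pre_ms,
        post_ms=config.post_ms if post_ms is None else post_ms,
        post_from=post_from,
    )
    logger.info("segmented %d trials (%s)", trials.n_trials,
                {lab: trials.labels.count(lab) for lab in sorted(set(trials.labels))})
    return prelag, trials, ser
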