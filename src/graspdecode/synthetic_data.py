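"""Synthetic EEG / hand-kinematics recordings with known ground truth.

The generator emulates the statistical structure the decoding analysis
assumes, at the study's scale: 64-channel EEG at 1000 Hz, 15 joint angles,
five grasped objects with 50 trials each, mean movement time 1.9 +/- 0.3 s.

Forward model
-------------
Each trial draws a per-object synergy *velocity* profile for three latent
components (two opposing Gaussian bumps: hand opening during the reach and
closing around the object, with object-specific amplitudes and timings).
Joint angular velocities are a fixed orthonormal loading matrix ``W_true``
(15 x 3) applied to those components plus small sensor noise; joint angles
are their cumulative integral.

Scalp EEG amplitude on a small set of informative channels is a *causally
leading* lagged mixture of the position-domain (time-integrated) synergy
trajectories::

    EEG[n, t] = sum_c sum_k G[n, k, c] * P_c[t + k] + noise

with coupling lags ``k`` concentrated at 40-100 ms. Coupling the EEG
*amplitude* to the position domain means that after the standard processing
chain — which differentiates EEG — the processed EEG is a lagged linear
function of the velocity-domain synergies the decoder targets; coupling
amplitude directly to velocities would leave a 90-degree phase mismatch that
no 100 ms lag filter could absorb.

Noise is white plus 1/f (spectrally shaped white noise). Its amplitude is
set per channel so that the coupling-signal to noise variance ratio within
the 0.1-1 Hz analysis band — the only band that survives preprocessing —
equals the requested SNR. An optional frontal ocular-artifact component
(spatial pattern x low-frequency random walk) is off by default.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io_core import (
    DEFAULT_MONTAGE_64,
    JOINT_LABELS,
    OBJECTS,
    Recording,
    TrialEvent,
)

__all__ = [
    "BumpProfile",
    "SyntheticSpec",
    "GroundTruth",
    "simulate_recording",
    "snr_sweep",
    "default_object_profiles",
    "make_w_true",
]

#: Channels carrying the kinematic coupling: contralateral (left)
#: sensorimotor and parietal sites, mirroring where grasp information is
#: expected on the scalp. Deliberately disjoint from the four frontal
#: channels used in the ocular-artifact omission control.
DEFAULT_INFORMATIVE: tuple[str, ...] = (
    "C1", "FC1", "C3", "CP5", "CP3", "P3", "P1", "CP1",
)

#: Default artifact topography: strongest at the fronto-polar sites.
ARTIFACT_PATTERN: dict[str, float] = {
    "Fp1": 1.0, "Fp2": 1.0, "AF7": 0.8, "AF8": 0.8, "AF3": 0.6, "AF4": 0.6,
    "F7": 0.3, "F8": 0.3, "F3": 0.2, "F4": 0.2,
}


@dataclass(frozen=True)
class BumpProfile:
    """Velocity profile of one synergy within one object's grasp.

    Two Gaussian bumps in normalized movement time: opening (amplitude
    ``a1`` deg/s, centre ``mu1``, width ``w1``) and an opposing closing bump
    at ``mu2`` / ``w2`` whose amplitude is chosen so the net displacement
    over the movement is zero (the hand returns through its resting
    posture between trials).
    """

    a1: float
    mu1: float
    w1: float
    mu2: float
    w2: float

    def velocity(self, tau: np.ndarray) -> np.ndarray:
        a2 = -self.a1 * self.w1 / self.w2
        return (
            self.a1 * np.exp(-0.5 * ((tau - self.mu1) / self.w1) ** 2)
            + a2 * np.exp(-0.5 * ((tau - self.mu2) / self.w2) ** 2)
        )


def default_object_profiles() -> dict[str, tuple[BumpProfile, BumpProfile, BumpProfile]]:
    """Per-object profiles for the three synergies.

    The three components have distinct temporal structure — aperture
    opening/closing mid-movement, finger spread early, thumb late — so
    their time courses are only weakly correlated and PCA separates them
    cleanly. Amplitudes are set so the population variance is dominated by
    grasp aperture (roughly 50/30/20 after preprocessing). Objects differ
    in amplitude, overall timing (whole-hand grasps open early, precision
    grasps late) and bump width, making the five grasps pairwise
    distinguishable from the trajectories while keeping the shared
    open-then-close morphology.
    """
    P = BumpProfile

    def trio(a1: float, a2: float, a3: float, d: float, w: float):
        return (
            P(a1, 0.20 + d, 0.06 * w, 0.78 + d, 0.06 * w),
            P(a2, 0.10 + d, 0.04 * w, 0.40 + d, 0.05 * w),
            P(a3, 0.55 + d, 0.04 * w, 0.93 + d, 0.04 * w),
        )

    return {
        "can":         trio(30.0, 22.0, 14.0, -0.08, 1.00),
        "card":        trio(17.0, 32.0, 18.0, -0.03, 1.50),
        "cd":          trio(27.0, 27.0, 12.0, 0.02, 0.80),
        "penny":       trio(13.0, 14.0, 24.0, 0.06, 1.25),
        "screwdriver": trio(24.0, 19.0, 28.0, 0.10, 1.00),
    }


def make_w_true() -> np.ndarray:
    """Fixed orthonormal 15 x 3 synergy loading matrix.

    Column 1 loads on finger MCP/PIP joints (aperture), column 2 on the
    abduction joints (spread), column 3 on the thumb; columns are
    orthonormalized by QR and sign-fixed so each column's largest-magnitude
    loading is positive.
    """
    raw = np.zeros((15, 3))
    #                MCPx4         PIPx4          thumb x3    ABD x4
    raw[:, 0] = [1.0, 1.0, 0.9, 0.8, 1.2, 1.2, 1.1, 1.0, 0.3, 0.3, 0.2, 0.1, 0.1, 0.1, 0.1]
    raw[:, 1] = [0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.0, 0.0, 1.0, 1.1, 1.0, 0.9]
    raw[:, 2] = [0.1, 0.0, 0.0, 0.0, 0.1, 0.0, 0.0, 0.0, 1.2, 1.0, 0.8, 0.2, 0.1, 0.0, 0.0]
    q, _ = np.linalg.qr(raw)
    w = q[:, :3]
    for c in range(3):
        if w[np.argmax(np.abs(w[:, c])), c] < 0:
            w[:, c] = -w[:, c]
    return w


@dataclass
class SyntheticSpec:
    """Generation parameters; defaults match the study conditions."""

    n_channels: int = 64
    fs: float = 1000.0
    trials_per_object: int = 50
    objects: tuple[str, ...] = OBJECTS
    duration_mean: float = 1.9      # s, movement time
    duration_sd: float = 0.3
    rest_range: tuple[float, float] = (1.0, 2.0)   # inter-trial rest, s
    lead_in: float = 3.0            # s of baseline before the first trial
    tail: float = 3.5               # s of baseline after the last offset
    snr: float = 10.0               # in-band signal/noise ratio, informative chans
    white_sd: float = 1.0           # relative white-noise amplitude
    pink_exponent: float = 1.0      # 1/f^a spectral slope of the colored part
    pink_amp: float = 1.0           # relative 1/f amplitude
    sensor_noise_sd: float = 0.5    # deg/s on joint velocities
    informative_channels: tuple[str, ...] = DEFAULT_INFORMATIVE
    coupling_lag_range_ms: tuple[float, float] = (40.0, 100.0)
    lag_grid_ms: tuple[float, ...] = tuple(float(v) for v in range(0, 101, 10))
    amplitude_jitter: float = 0.05  # trial-to-trial multiplicative sd
    timing_jitter: float = 0.02     # trial-to-trial bump-centre sd (fractions)
    motor_noise_frac: float = 0.85  # idiosyncratic fraction of trial variance
    motor_noise_smooth_s: float = 0.08  # smoothness of the idiosyncratic part
    artifact: bool = False
    artifact_amp: float = 20.0      # microvolt-scale artifact std
    channel_labels: tuple[str, ...] = DEFAULT_MONTAGE_64
    object_profiles: dict[str, tuple[BumpProfile, ...]] = field(
        default_factory=default_object_profiles)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_object < 1:
            raise ValueError("trials_per_object must be >= 1")
        self.channel_labels = tuple(self.channel_labels)[: self.n_channels]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("not enough channel labels for n_channels")
        missing = set(self.informative_channels) - set(self.channel_labels)
        if missing:
            raise ValueError(f"informative channels not in montage: {sorted(missing)}")
        if not self.informative_channels:
            raise ValueError("empty coupling: no informative channels")
        lo, hi = self.coupling_lag_range_ms
        if not (0 <= lo < hi <= 100):
            raise ValueError("coupling lags must lie within [0, 100] ms")
        missing_obj = set(self.objects) - set(self.object_profiles)
        if missing_obj:
            raise ValueError(f"objects without profiles: {sorted(missing_obj)}")


@dataclass
class GroundTruth:
    """Everything needed to verify downstream recovery.

    ``pc_velocity`` / ``pc_position`` are the full-length latent synergy
    tracks (3 x n_samples) in velocity and position domain; ``coupling`` is
    the channels x lags x components tensor on the generator's 10 ms lag
    grid. Reconstructing joint velocities as ``w_true @ pc_velocity``
    reproduces the noiseless kinematics exactly.
    """

    w_true: np.ndarray
    coupling: np.ndarray
    lag_grid_ms: tuple[float, ...]
    pc_velocity: np.ndarray
    pc_position: np.ndarray
    trial_labels: list[str]
    informative_channels: tuple[str, ...]
    seed: int


def _pink_noise(rng: np.random.Generator, n_samples: int, fs: float,
                exponent: float) -> np.ndarray:
    """1/f^exponent noise via spectral shaping of white noise, unit std."""
    spec = np.fft.rfft(rng.standard_normal(n_samples))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_variance(x: np.ndarray, fs: float, band=(0.1, 1.0)) -> np.ndarray:
    """Variance of each row of ``x`` within the analysis band."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1).var(axis=-1)


def _draw_coupling(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Coupling tensor G (channels x lags x 3), nonzero only on the
    informative set and within the configured lag range."""
    lags = np.asarray(spec.lag_grid_ms)
    lo, hi = spec.coupling_lag_range_ms
    g = np.zeros((spec.n_channels, len(lags), 3))
    idx = [spec.channel_labels.index(ch) for ch in spec.informative_channels]
    for n in idx:
        for c in range(3):
            centre = rng.uniform(max(lo, 60.0), min(hi, 90.0))
            amp = rng.normal(0.0, 1.0)
            # avoid vanishing channels: keep |amp| away from zero
            amp += math.copysign(0.3, amp if amp != 0 else 1.0)
            envelope = np.exp(-0.5 * ((lags - centre) / 15.0) ** 2)
            envelope[(lags < lo) | (lags > hi)] = 0.0
            g[n, :, c] = amp * envelope
    return g


def _trial_timeline(spec: SyntheticSpec, rng: np.random.Generator):
    """Pseudorandom object sequence, onsets/offsets in samples."""
    labels = list(spec.objects) * spec.trials_per_object
    rng.shuffle(labels)
    n_trials = len(labels)
    durations = np.clip(
        rng.normal(spec.duration_mean, spec.duration_sd, n_trials),
        max(0.4, spec.duration_mean - 3 * spec.duration_sd),
        spec.duration_mean + 3 * spec.duration_sd,
    )
    rests = rng.uniform(*spec.rest_range, n_trials)
    onsets = np.empty(n_trials, dtype=int)
    offsets = np.empty(n_trials, dtype=int)
    t = spec.lead_in
    for i in range(n_trials):
        onsets[i] = int(round(t * spec.fs))
        offsets[i] = onsets[i] + int(round(durations[i] * spec.fs))
        t = offsets[i] / spec.fs + rests[i]
    n_samples = offsets[-1] + int(round(spec.tail * spec.fs))
    return labels, onsets, offsets, n_samples


def simulate_recording(spec: SyntheticSpec) -> tuple[Recording, GroundTruth]:
    """Generate one synthetic recording plus its ground truth.

    Identical specs (including seed) yield byte-identical output. The SNR
    parameter scales the noise only — signal content and noise realization
    are drawn before scaling — so an SNR sweep changes nothing else.
    """
    rng = np.random.default_rng(spec.seed)
    w_true = make_w_true()
    coupling = _draw_coupling(spec, rng)
    labels, onsets, offsets, n_samples = _trial_timeline(spec, rng)

    # latent synergy velocity tracks, zero during rest. Each trial is the
    # object's profile plus smooth trial-idiosyncratic motor variability in
    # synergy space: single-trial grasps are far from stereotyped, and it is
    # this idiosyncrasy (shared by EEG and kinematics through the coupling)
    # that makes scrambled-pairing surrogates decode at chance while true
    # pairs decode well.
    from scipy.ndimage import gaussian_filter1d

    f = spec.motor_noise_frac
    if not (0 <= f < 1):
        raise ValueError("motor_noise_frac must lie in [0, 1)")
    pc_vel = np.zeros((3, n_samples))
    for lab, a, b in zip(labels, onsets, offsets):
        dur = b - a
        tau = np.arange(dur) / dur
        taper = np.minimum(1.0, np.minimum(tau, 1.0 - tau) / 0.1)  # soft edges
        for c, prof in enumerate(spec.object_profiles[lab][:3]):
            amp = 1.0 + spec.amplitude_jitter * rng.standard_normal()
            shift = spec.timing_jitter * rng.standard_normal()
            jittered = dataclasses.replace(
                prof, a1=prof.a1 * amp,
                mu1=prof.mu1 + shift, mu2=prof.mu2 + shift)
            common = jittered.velocity(tau)
            track = common
            if f > 0:
                idio = gaussian_filter1d(
                    rng.standard_normal(dur),
                    sigma=max(spec.motor_noise_smooth_s * spec.fs, 1.0))
                idio *= taper
                idio -= taper * (idio.sum() / taper.sum())  # zero net motion
                sd = idio.std()
                if sd > 0:
                    idio *= np.sqrt(f / (1.0 - f)) * common.std() / sd
                track = common + idio
            pc_vel[c, a:b] += track
    pc_pos = np.cumsum(pc_vel, axis=1) / spec.fs

    # EEG signal: causally leading lagged mixture of position-domain synergies
    eeg_signal = np.zeros((spec.n_channels, n_samples))
    for k, lag_ms in enumerate(spec.lag_grid_ms):
        shift = int(round(lag_ms / 1000.0 * spec.fs))
        gk = coupling[:, k, :]                       # channels x comps
        if not np.any(gk):
            continue
        if shift == 0:
            eeg_signal += gk @ pc_pos
        else:
            eeg_signal[:, :-shift] += gk @ pc_pos[:, shift:]

    # noise: white + 1/f, scaled per channel to the requested in-band SNR
    white = rng.standard_normal((spec.n_channels, n_samples))
    pink = np.stack([
        _pink_noise(rng, n_samples, spec.fs, spec.pink_exponent)
        for _ in range(spec.n_channels)
    ])
    noise = spec.white_sd * white + spec.pink_amp * pink

    info_idx = np.array([spec.channel_labels.index(c)
                         for c in spec.informative_channels])
    if math.isinf(spec.snr):
        scale = np.zeros(spec.n_channels)
    else:
        sig_bv = _band_variance(eeg_signal[info_idx], spec.fs)
        noi_bv = _band_variance(noise[info_idx], spec.fs)
        per_info = np.sqrt(sig_bv / (spec.snr * noi_bv))
        scale = np.full(spec.n_channels, per_info.mean())
        scale[info_idx] = per_info
    eeg = eeg_signal + noise * scale[:, None]

    if spec.artifact:
        walk = np.cumsum(rng.standard_normal(n_samples))
        walk = sps.detrend(walk)
        walk *= spec.artifact_amp / max(walk.std(), 1e-12)
        for ch, w in ARTIFACT_PATTERN.items():
            if ch in spec.channel_labels:
                eeg[spec.channel_labels.index(ch)] += w * walk

    # kinematics: velocities through the loading matrix, angles by integration
    vel = w_true @ pc_vel
    if spec.sensor_noise_sd > 0:
        vel = vel + spec.sensor_noise_sd * rng.standard_normal(vel.shape)
    rest_posture = np.linspace(5.0, 35.0, 15)[:, None]   # resting joint angles
    angles = rest_posture + np.cumsum(vel, axis=1) / spec.fs

    events = [TrialEvent(int(a), int(b), lab)
              for a, b, lab in zip(onsets, offsets, labels)]
    rec = Recording(eeg=eeg, fs=spec.fs, channel_labels=spec.channel_labels,
                    kin=angles, joint_labels=JOINT_LABELS, events=events)
    truth = GroundTruth(
        w_true=w_true, coupling=coupling, lag_grid_ms=spec.lag_grid_ms,
        pc_velocity=pc_vel, pc_position=pc_pos, trial_labels=list(labels),
        informative_channels=spec.informative_channels, seed=spec.seed,
    )
    return rec, truth


def snr_sweep(spec: SyntheticSpec, snr_values: list[float]) -> list[Recording]:
    """Recordings identical except for the noise scaling.

    Every entry reuses the spec's seed, so signal content and the noise
    realization are shared; only the per-channel noise scale differs.
    """
    if not snr_values:
        raise ValueError("snr_values must be non-empty")
    for v in snr_values:
        if not (v > 0):
            raise ValueError(f"SNR values must be positive, got {v}")
    out = []
    for v in snr_values:
        rec, _ = simulate_recording(dataclasses.replace(spec, snr=float(v)))
        out.append(rec)
    return out
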