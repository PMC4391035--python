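"""Shared test helpers: tiny container builders and on-the-fly vendor files."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from graspdecode import JOINT_LABELS, Recording, TrialSet


def make_trialset(eeg_trials=None, vel_trials=None, labels=None, *,
                  n_trials=3, t_len=40, n_channels=3, n_lags=4, fs=100.0,
                  rng=None) -> TrialSet:
    """A TrialSet filled with random data unless arrays are supplied."""
    rng = rng or np.random.default_rng(0)
    if eeg_trials is None:
        eeg_trials = [rng.standard_normal((t_len, n_channels, n_lags))
                      for _ in range(n_trials)]
    if vel_trials is None:
        vel_trials = [rng.standard_normal((e.shape[0], 15)) for e in eeg_trials]
    if labels is None:
        objects = ["can", "card", "cd", "penny", "screwdriver"]
        labels = [objects[i % 5] for i in range(len(eeg_trials))]
    n_channels = eeg_trials[0].shape[1]
    n_lags = eeg_trials[0].shape[2]
    return TrialSet(
        eeg=eeg_trials, velocities=vel_trials, labels=labels,
        channel_labels=tuple(f"ch{i}" for i in range(n_channels)),
        joint_labels=JOINT_LABELS, fs=fs, L=n_lags - 1, lag_step=1,
    )


def sine_recording(freq: float, fs: float, dur: float, amp: float = 1.0,
                   n_channels: int = 1) -> Recording:
    t = np.arange(int(dur * fs)) / fs
    x = amp * np.sin(2 * np.pi * freq * t)
    return Recording(eeg=np.tile(x, (n_channels, 1)), fs=fs,
                     channel_labels=tuple(f"ch{i}" for i in range(n_channels)))


def write_brainvision(tmp: Path, data: np.ndarray, fs: float,
                      labels, markers=()) -> Path:
    """Emit a minimal BrainVision triplet (.vhdr/.vmrk text + float32 .eeg).

    ``markers``: iterable of (description, one_based_position).
    """
    n_ch = data.shape[0]
    chan_lines = "\n".join(
        f"Ch{i + 1}={lab},,1,µV" for i, lab in enumerate(labels))
    (tmp / "test.vhdr").write_text(
        "Brain Vision Data Exchange Header File Version 1.0\n"
        "[Common Infos]\nDataFile=test.eeg\nMarkerFile=test.vmrk\n"
        "DataFormat=BINARY\nDataOrientation=MULTIPLEXED\n"
        f"NumberOfChannels={n_ch}\nSamplingInterval={int(1e6 / fs)}\n"
        "[Binary Infos]\nBinaryFormat=IEEE_FLOAT_32\n"
        f"[Channel Infos]\n{chan_lines}\n")
    marker_lines = ["Mk1=New Segment,,1,1,0,0"]
    for j, (desc, pos) in enumerate(markers, start=2):
        marker_lines.append(f"Mk{j}=Stimulus,{desc},{pos},1,0")
    (tmp / "test.vmrk").write_text(
        "Brain Vision Data Exchange Marker File, Version 1.0\n"
        "[Common Infos]\nDataFile=test.eeg\n"
        "[Marker Infos]\n" + "\n".join(marker_lines) + "\n")
    data.T.astype("<f4").tofile(tmp / "test.eeg")
    return tmp / "test.vhdr"


def write_edf(tmp: Path, data: np.ndarray, fs: float, labels,
              phys_range=(-200.0, 200.0)) -> Path:
    """Emit a minimal 16-bit EDF file (one-second records)."""
    n_sig, n_samp = data.shape
    spr = int(fs)
    if n_samp % spr:
        raise ValueError("test data must fill whole 1 s records")
    n_rec = n_samp // spr
    pmin, pmax = phys_range
    dmin, dmax = -32768, 32767

    def pad(s, n):
        return str(s)[:n].ljust(n)

    hdr = pad("0", 8) + pad("X", 80) + pad("X", 80)
    hdr += pad("01.01.20", 8) + pad("00.00.00", 8)
    hdr += pad(256 * (1 + n_sig), 8) + pad("", 44) + pad(n_rec, 8)
    hdr += pad(1, 8) + pad(n_sig, 4)
    for lab in labels:
        hdr += pad(lab, 16)
    for width, value in ((80, ""), (8, "uV"), (8, pmin), (8, pmax),
                         (8, dmin), (8, dmax), (80, ""), (8, spr), (32, "")):
        for _ in range(n_sig):
            hdr += pad(value, width)
    dig = np.round((data - pmin) / (pmax - pmin) * (dmax - dmin) + dmin)
    dig = dig.astype("<i2")
    path = tmp / "test.edf"
    with open(path, "wb") as fh:
        fh.write(hdr.encode("ascii"))
        for r in range(n_rec):
            for s in range(n_sig):
                fh.write(dig[s, r * spr:(r + 1) * spr].tobytes())
    return path
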