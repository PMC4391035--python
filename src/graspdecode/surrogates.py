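"""Empirical chance levels via surrogate EEG.

Two surrogate constructions destroy the EEG-kinematics association while
preserving the marginal signal statistics:

* **phase scrambling** — per channel, the Fourier phases of the continuous
  band-limited EEG are replaced by uniform random phases (conjugate
  symmetry enforced) while the magnitude spectrum, and hence the
  autocovariance, is kept bit-exact. Time-domain decoding relies on phase
  locking between EEG and kinematics, so decodability should collapse.
* **fold scrambling** — the pairing between EEG and kinematics across
  trials is permuted (a derangement, so no trial keeps its own EEG) while
  kinematics and labels stay in place.

Running the full cross-validated decoder on such surrogates, several
repetitions each, yields the empirical null distribution of the median
correlation metric.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np

from .io_core import PipelineConfig, Recording
from .preprocessing import TrialSet, lag_embed, segment_trials
from .wiener_decoding import cross_validate

logger = logging.getLogger(__name__)

__all__ = ["NullResult", "phase_scramble", "fold_scramble", "chance_level_suite"]


@dataclass
class NullResult:
    """Decoding accuracy under a surrogate null.

    ``rep_median_r[j, i]`` is repetition ``j``'s median cross-validated r
    for output ``i``; ``mean`` / ``sem`` pool over repetitions. ``seeds``
    records the per-repetition seeds so a rerun reproduces the result
    exactly.
    """

    method: str
    repetitions: int
    rep_median_r: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    output_names: tuple[str, ...]
    seeds: tuple[int, ...]


def phase_scramble(rec: Recording, seed: int = 0) -> Recording:
    """Randomize each EEG channel's Fourier phases, keeping magnitudes.

    Phases are drawn independently per channel; DC and (for even length)
    the Nyquist bin keep their values so the output is exactly real.
    Kinematics and events are untouched.
    """
    if rec.n_samples == 0:
        raise ValueError("empty signal")
    rng = np.random.default_rng(seed)
    n = rec.n_samples
    spec = np.fft.rfft(rec.eeg, axis=-1)
    n_bins = spec.shape[-1]
    # bins strictly between DC and (even-n) Nyquist get random phases
    free = slice(1, n_bins - 1 if n % 2 == 0 else n_bins)
    phases = rng.uniform(0.0, 2.0 * np.pi, (rec.n_channels, len(range(*free.indices(n_bins)))))
    out = spec.copy()
    out[:, free] = np.abs(spec[:, free]) * np.exp(1j * phases)
    scrambled = np.fft.irfft(out, n=n, axis=-1)
    return rec.replace(eeg=scrambled)


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Sattolo's algorithm: a uniformly random cyclic permutation, which is
    always fixed-point free for n >= 2."""
    if n < 2:
        raise ValueError("need at least 2 trials to scramble the pairing")
    perm = np.arange(n)
    for i in range(n - 1, 0, -1):
        j = int(rng.integers(0, i))
        perm[i], perm[j] = perm[j], perm[i]
    return perm


def fold_scramble(trials: TrialSet, seed: int = 0) -> TrialSet:
    """Permute EEG across trials while kinematics and labels stay put.

    The permutation is a derangement, so no trial keeps its own EEG. When
    paired trials differ in length, both sides are truncated to the shorter
    (logged).
    """
    perm = _derangement(trials.n_trials, np.random.default_rng(seed))
    eeg, vel, pcs = [], [], []
    n_trunc = 0
    for i, j in enumerate(perm):
        e = trials.eeg[j]
        v = trials.velocities[i]
        t = min(e.shape[0], v.shape[0])
        if e.shape[0] != v.shape[0]:
            n_trunc += 1
        eeg.append(e[:t])
        vel.append(v[:t])
        if trials.pcs is not None:
            pcs.append(trials.pcs[i][:t])
    if n_trunc:
        logger.info("fold scramble truncated %d mismatched trial pairs", n_trunc)
    return dataclasses.replace(
        trials, eeg=eeg, velocities=vel,
        pcs=pcs if trials.pcs is not None else None,
    )


def chance_level_suite(data: Recording | TrialSet,
                       config: PipelineConfig | None = None, *,
                       method: str | None = None,
                       repetitions: int = 5, seed: int = 0) -> NullResult:
    """Decode surrogate data ``repetitions`` times and pool the accuracy.

    ``data`` selects the method: a continuous pre-lag-embedding
    :class:`Recording` (band-limited, downsampled, differentiated, with
    velocity kinematics and rescaled events) runs phase scrambling; a
    segmented :class:`TrialSet` runs fold scrambling. Repetition ``j``
    uses seed ``seed + j`` (logged), so a rerun reproduces the result.
    """
    config = config or PipelineConfig()
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    if method is None:
        method = "phase" if isinstance(data, Recording) else "fold"
    if method not in ("phase", "fold"):
        raise ValueError(f"method must be 'phase' or 'fold', got {method!r}")
    if method == "phase" and not isinstance(data, Recording):
        raise TypeError("phase scrambling needs the continuous Recording stage")
    if method == "fold" and not isinstance(data, TrialSet):
        raise TypeError("fold scrambling needs a segmented TrialSet")

    seeds = tuple(seed + j for j in range(repetitions))
    rows = []
    names: tuple[str, ...] = ()
    for rep_seed in seeds:
        if method == "phase":
            scrambled = phase_scramble(data, seed=rep_seed)
            lagged = lag_embed(scrambled, L=config.max_lag, step=config.lag_step)
            trials = segment_trials(lagged, scrambled,
                                    pre_ms=config.pre_ms, post_ms=config.post_ms)
        else:
            trials = fold_scramble(data, seed=rep_seed)
        res = cross_validate(
            trials, folds=config.cv_folds, seed=config.seed,
            fold_safe=config.fold_safe, n_synergies=config.n_synergies,
        )
        rows.append(res.median_r)
        names = res.output_names
        logger.info("%s surrogate rep seed %d: median r = %s",
                    method, rep_seed, np.round(res.median_r, 4))
    rep = np.vstack(rows)
    sem = rep.std(axis=0, ddof=1) / np.sqrt(repetitions) if repetitions > 1 \
        else np.zeros(rep.shape[1])
    return NullResult(
        method=method, repetitions=repetitions, rep_median_r=rep,
        mean=rep.mean(axis=0), sem=sem, output_names=names, seeds=seeds,
    )
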