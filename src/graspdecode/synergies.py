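"""Kinematic synergies: PCA of the 15 joint angular velocities.

Grasping is controlled in a low-dimensional synergy space; decomposing the
joint angular velocities into principal components recovers it. The first
component typically captures grasp aperture (finger MCP/PIP flexion), the
second finger spread (abduction), the third independent thumb motion.

PCA is performed on the covariance of the stacked (sum-of-trial-lengths x
15) velocity matrix with centering but no per-joint rescaling: all joints
share units (deg/s), so the variance split is physically meaningful.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .preprocessing import TrialSet

__all__ = ["SynergyModel", "fit_synergies", "project", "inverse_project"]


@dataclass
class SynergyModel:
    """PCA decomposition of joint angular velocities.

    ``loadings`` is orthonormal (15 x 15, columns = components ordered by
    explained variance); ``variance_fractions`` is non-negative,
    non-increasing and sums to 1. Sign convention: each column's
    largest-magnitude loading is positive.
    """

    mean: np.ndarray                  # (15,), deg/s
    loadings: np.ndarray              # (15, 15)
    variance_fractions: np.ndarray    # (15,)
    retained: int
    joint_labels: tuple[str, ...]

    @property
    def total_variance(self) -> float:
        """Trace of the velocity covariance the model was fitted on."""
        return float(self._total_variance)

    _total_variance: float = 0.0


def fit_synergies(trials: TrialSet, retained: int = 3) -> SynergyModel:
    """Eigendecompose the covariance of the stacked joint velocities."""
    x = trials.stacked_velocities()
    n, j = x.shape
    if n <= j:
        raise ValueError(f"need more than {j} samples to fit synergies, got {n}")
    mean = x.mean(axis=0)
    cov = np.cov(x - mean, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for c in range(evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, c])), c] < 0:
            evecs[:, c] = -evecs[:, c]
    total = evals.sum()
    fractions = evals / total if total > 0 else np.full(j, 1.0 / j)
    model = SynergyModel(
        mean=mean, loadings=evecs, variance_fractions=fractions,
        retained=retained, joint_labels=trials.joint_labels,
    )
    model._total_variance = float(total)
    return model


def project(trials: TrialSet, model: SynergyModel) -> TrialSet:
    """Fill ``trials.pcs`` with the retained synergy trajectories.

    ``pcs = (velocities - mean) @ loadings[:, :retained]``; projecting with
    all 15 components and inverting reconstructs the velocities exactly.
    """
    if trials.joint_labels != model.joint_labels:
        raise ValueError("joint labels of trials and model disagree")
    w = model.loadings[:, : model.retained]
    pcs = [(v - model.mean) @ w for v in trials.velocities]
    return dataclasses.replace(trials, pcs=pcs)


def inverse_project(pc_full: np.ndarray, model: SynergyModel) -> np.ndarray:
    """Map full 15-component scores back to joint velocities."""
    return pc_full @ model.loadings.T + model.mean
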