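"""Lagged linear (Wiener) decoding of grasp kinematics from EEG.

The decoder predicts each kinematic output (synergy trajectory or joint
angular velocity) as an affine function of the preprocessed EEG over all
channels and lags::

    y_i[t] = b0_i + sum_n sum_k beta[n, k, i] * EEG_n[t - k]

fitted by ordinary least squares on training data. Accuracy is assessed by
stratified 8-fold cross-validation as the median across folds of the
Pearson correlation between predicted and observed output samples.

On top of the decoder this module provides:

* channel ranking ``R_n`` — mean over lags of the root-sum-square of the
  first three synergy coefficients, computed from a full-dataset fit;
* best-N accuracy curves with a double-exponential fit to locate the peak
  channel count robustly;
* per-lag contribution percentages ``%T_k`` and the channel x lag map for
  scalp plotting;
* t-distribution significance of per-fold correlations with Bonferroni
  correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.model_selection import KFold, StratifiedKFold

from .io_core import PipelineConfig, Recording
from .preprocessing import TrialSet, preprocess, standardize
from .synergies import fit_synergies, project

logger = logging.getLogger(__name__)

__all__ = [
    "WienerModel",
    "DecodingResult",
    "ChannelRanking",
    "LagContribution",
    "AccuracyCurve",
    "fit_wiener",
    "predict",
    "cross_validate",
    "rank_channels",
    "accuracy_vs_channels",
    "lag_contributions",
    "assess_significance",
    "fit_full",
    "decode_recording",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class WienerModel:
    """OLS coefficients over (channel, lag, output) plus intercepts."""

    intercepts: np.ndarray            # (n_outputs,)
    coef: np.ndarray                  # (channels, L+1, n_outputs)
    channel_labels: tuple[str, ...]
    L: int
    output_names: tuple[str, ...]

    @property
    def coef_flat(self) -> np.ndarray:
        """(C*(L+1), n_outputs) view matching the design-matrix layout."""
        return self.coef.reshape(-1, self.coef.shape[2])


@dataclass
class DecodingResult:
    """Cross-validated decoding accuracy.

    ``fold_r[f, i]`` is the Pearson correlation between predicted and
    observed output ``i`` over the concatenated test samples of fold ``f``;
    ``median_r`` is the median across folds. ``fold_assignment[j]`` is the
    test fold of trial ``j`` (a partition). ``predictions``/``observed``
    hold per-trial test trajectories in trial order.
    """

    fold_r: np.ndarray                # (folds, n_outputs)
    median_r: np.ndarray              # (n_outputs,)
    output_names: tuple[str, ...]
    fold_assignment: np.ndarray       # (n_trials,)
    test_sample_counts: np.ndarray    # (folds,)
    predictions: list[np.ndarray]
    observed: list[np.ndarray]


@dataclass
class ChannelRanking:
    """Per-channel relevance ``R_n`` and the descending rank order."""

    r_n: np.ndarray
    order: np.ndarray                 # channel indices, best first
    channel_labels: tuple[str, ...]

    def top(self, n: int) -> tuple[str, ...]:
        return tuple(self.channel_labels[i] for i in self.order[:n])


@dataclass
class LagContribution:
    """Per-lag percentages (summing to 100) and the channel x lag map."""

    percent: np.ndarray               # (L+1,)
    channel_lag_map: np.ndarray       # (channels, L+1), unnormalized
    channel_labels: tuple[str, ...]


@dataclass
class AccuracyCurve:
    """Median-r as a function of the number of best-ranked channels."""

    n_values: np.ndarray              # (C,) channel counts 1..C
    curve: np.ndarray                 # (C, n_outputs)
    params: np.ndarray | None         # (n_outputs, 4) double-exponential (a,b,c,d)
    peak_n: np.ndarray                # (n_outputs,) int
    peak_r: np.ndarray                # (n_outputs,)
    output_names: tuple[str, ...]


# ---------------------------------------------------------------------------
# Fitting and prediction
# ---------------------------------------------------------------------------

def _targets(trials: TrialSet, outputs: str) -> tuple[np.ndarray, tuple[str, ...]]:
    if outputs == "pcs":
        y = trials.stacked_pcs()
        names = tuple(f"PC{i + 1}" for i in range(y.shape[1]))
    elif outputs in ("joints", "velocities"):
        y = trials.stacked_velocities()
        names = trials.joint_labels
    else:
        raise ValueError(f"outputs must be 'pcs' or 'joints', got {outputs!r}")
    return y, names


def fit_wiener(train: TrialSet, outputs: str = "pcs") -> WienerModel:
    """Least-squares fit of the lagged linear decoder.

    Minimizes the squared error via the normal equations on the flattened
    (channel, lag) design matrix with an explicit intercept column — the
    Gram matrix is p x p, so the solve stays cheap even for hour-long
    recordings — with one joint solve for all outputs. A rank-deficient
    design (e.g. duplicated channels) yields the minimum-norm solution
    with a warning.
    """
    x = train.design_matrix()
    y, names = _targets(train, outputs)
    n, p = x.shape
    if n < p + 1:
        raise ValueError(
            f"need at least {p + 1} training samples for {p} features, got {n}")
    xd = np.column_stack([x, np.ones(n)])
    gram = xd.T @ xd
    rhs = xd.T @ y
    # lstsq on the Gram system returns the same minimum-norm solution as
    # the design-matrix pseudoinverse when the system is consistent
    beta, _, rank, _ = np.linalg.lstsq(gram, rhs, rcond=None)
    if rank < p + 1:
        logger.warning(
            "rank-deficient design (rank %d < %d); minimum-norm solution",
            rank, p + 1)
    n_out = y.shape[1]
    coef = beta[:p].reshape(train.n_channels, train.L + 1, n_out)
    return WienerModel(
        intercepts=beta[p], coef=coef,
        channel_labels=train.channel_labels, L=train.L, output_names=names,
    )


def predict(model: WienerModel, trials: TrialSet) -> list[np.ndarray]:
    """Apply the decoder; one (T_i, n_outputs) trajectory per trial."""
    if trials.channel_labels != model.channel_labels or trials.L != model.L:
        raise ValueError("trial (channel, lag) layout does not match the model")
    w = model.coef_flat
    return [e.reshape(e.shape[0], -1) @ w + model.intercepts for e in trials.eeg]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        warnings.warn("zero-variance series in correlation; recording r = 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _fold_iterator(labels: list[str], folds: int, seed: int):
    y = np.asarray(labels)
    counts = np.unique(y, return_counts=True)[1]
    if len(counts) > 1 and counts.min() >= folds:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    else:
        logger.warning("labels too sparse to stratify %d folds; plain K-fold", folds)
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    return splitter.split(np.zeros(len(y)), y)


def cross_validate(trials: TrialSet, folds: int = 8, seed: int = 0, *,
                   outputs: str = "pcs", fold_safe: bool = True,
                   n_synergies: int = 3) -> DecodingResult:
    """Stratified k-fold cross-validated decoding.

    In fold-safe mode (default) feature standardization and the synergy
    basis are fitted on the training trials of each fold and applied to the
    held-out trials, so no statistic leaks across the split. The
    alternative standardizes and fits the synergy PCA across all trials
    before folding, reproducing the original analysis at the cost of a mild
    leak.
    """
    if trials.n_trials < folds:
        raise ValueError(f"{trials.n_trials} trials cannot fill {folds} folds")

    if not fold_safe:
        base, stats_all = standardize(trials)
        if outputs == "pcs":
            base = project(base, fit_synergies(base, retained=n_synergies))
    else:
        base = trials

    n_out = n_synergies if outputs == "pcs" else 15
    fold_r = np.zeros((folds, n_out))
    counts = np.zeros(folds, dtype=int)
    assignment = np.full(trials.n_trials, -1, dtype=int)
    predictions: list[np.ndarray] = [None] * trials.n_trials  # type: ignore
    observed: list[np.ndarray] = [None] * trials.n_trials  # type: ignore
    names: tuple[str, ...] = ()

    for f, (tr_idx, te_idx) in enumerate(_fold_iterator(base.labels, folds, seed)):
        train, test = base.subset(tr_idx), base.subset(te_idx)
        if fold_safe:
            train, st = standardize(train)
            test, _ = standardize(test, stats=st)
            if outputs == "pcs":
                syn = fit_synergies(train, retained=n_synergies)
                train, test = project(train, syn), project(test, syn)
        model = fit_wiener(train, outputs=outputs)
        names = model.output_names
        preds = predict(model, test)
        obs = test.pcs if outputs == "pcs" else test.velocities
        pred_cat = np.concatenate(preds, axis=0)
        obs_cat = np.concatenate(obs, axis=0)
        counts[f] = pred_cat.shape[0]
        for i in range(n_out):
            fold_r[f, i] = _pearson(pred_cat[:, i], obs_cat[:, i])
        assignment[te_idx] = f
        for j, p, o in zip(te_idx, preds, obs):
            predictions[j] = p
            observed[j] = o

    return DecodingResult(
        fold_r=fold_r, median_r=np.median(fold_r, axis=0), output_names=names,
        fold_assignment=assignment, test_sample_counts=counts,
        predictions=predictions, observed=observed,
    )


# ---------------------------------------------------------------------------
# Channel ranking, best-N curves, lag contributions
# ---------------------------------------------------------------------------

def rank_channels(model: WienerModel) -> ChannelRanking:
    """Rank channels by mean-over-lags root-sum-square synergy coefficients.

    ``R_n = (1/(L+1)) * sum_k sqrt(sum_i beta[n,k,i]^2)`` over the three
    retained synergy outputs, from a model fitted on the entire dataset.
    Descending order, ties broken by channel index.
    """
    if model.coef.shape[2] < 3:
        raise ValueError("channel ranking requires the three synergy outputs")
    rss = np.sqrt((model.coef[:, :, :3] ** 2).sum(axis=2))   # (C, L+1)
    r_n = rss.mean(axis=1)
    order = np.argsort(-r_n, kind="stable")
    return ChannelRanking(r_n=r_n, order=order,
                          channel_labels=model.channel_labels)


def _double_exp(n, a, b, c, d):
    return a * np.exp(b * n) + c * np.exp(d * n)


def _fit_double_exponential(n: np.ndarray, y: np.ndarray, seed: int,
                            ) -> np.ndarray | None:
    """Multi-start nonlinear least squares for ``a e^{bn} + c e^{dn}``."""
    rng = np.random.default_rng(seed)
    scale = max(abs(y).max(), 1e-3)
    base_starts = [
        (scale, -0.01, -scale, -0.3),
        (scale, -0.05, -scale, -0.5),
        (scale, 0.005, -scale, -0.2),
        (y[-1], -0.001, y[0] - y[-1], -0.1),
    ]
    starts = list(base_starts)
    while len(starts) < 8:
        a0, b0, c0, d0 = base_starts[len(starts) % len(base_starts)]
        jit = rng.uniform(0.5, 1.5, 4)
        starts.append((a0 * jit[0], b0 * jit[1], c0 * jit[2], d0 * jit[3]))
    best, best_sse = None, np.inf
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(
                    _double_exp, n, y, p0=p0, maxfev=5000)
        except (RuntimeError, TypeError, FloatingPointError):
            continue
        resid = y - _double_exp(n, *popt)
        sse = float(resid @ resid)
        if np.isfinite(sse) and sse < best_sse:
            best, best_sse = popt, sse
    return best


def accuracy_vs_channels(trials: TrialSet, ranking: ChannelRanking,
                         folds: int = 8, seed: int = 0, *,
                         outputs: str = "pcs", fold_safe: bool = True,
                         n_synergies: int = 3) -> AccuracyCurve:
    """Cross-validated accuracy with the best N channels, N = 1..C.

    A double exponential is fitted to each output's curve (multi-start,
    seeded) and the peak is the integer argmax of the fit within
    [1, C]; if no start converges the raw-curve argmax is used with a
    warning. Note the ranking comes from a full-dataset fit, so the curves
    inherit that selection bias.
    """
    if set(ranking.channel_labels) != set(trials.channel_labels):
        raise ValueError("ranking and trials cover different channels")
    c_max = trials.n_channels
    rows = []
    for n_ch in range(1, c_max + 1):
        sub = trials.select_channels(ranking.top(n_ch))
        res = cross_validate(sub, folds=folds, seed=seed, outputs=outputs,
                             fold_safe=fold_safe, n_synergies=n_synergies)
        rows.append(res.median_r)
    curve = np.vstack(rows)                          # (C, n_outputs)
    n = np.arange(1, c_max + 1, dtype=float)
    n_out = curve.shape[1]
    params = np.full((n_out, 4), np.nan)
    peak_n = np.zeros(n_out, dtype=int)
    peak_r = np.zeros(n_out)
    for i in range(n_out):
        popt = _fit_double_exponential(n, curve[:, i], seed + i)
        if popt is None:
            logger.warning("double-exponential fit failed for output %d; "
                           "using raw-curve argmax", i)
            peak_n[i] = int(np.argmax(curve[:, i])) + 1
            peak_r[i] = curve[peak_n[i] - 1, i]
        else:
            params[i] = popt
            fitted = _double_exp(n, *popt)
            peak_n[i] = int(np.argmax(fitted)) + 1
            peak_r[i] = float(fitted[peak_n[i] - 1])
    return AccuracyCurve(
        n_values=n.astype(int), curve=curve,
        params=params, peak_n=peak_n, peak_r=peak_r,
        output_names=res.output_names,
    )


def lag_contributions(model: WienerModel) -> LagContribution:
    """Percentage contribution of each lag to the synergy decoding.

    ``%T_k = 100 * sum_n s[n,k] / sum_k sum_n s[n,k]`` with
    ``s[n,k] = sqrt(sum_i beta[n,k,i]^2)`` over the three synergy outputs;
    the unnormalized channel x lag map is exported for scalp plotting.
    """
    if model.coef.shape[2] < 3:
        raise ValueError("lag contributions require the three synergy outputs")
    s = np.sqrt((model.coef[:, :, :3] ** 2).sum(axis=2))     # (C, L+1)
    total = s.sum()
    if total == 0:
        raise ValueError("all-zero coefficients: contribution undefined")
    percent = 100.0 * s.sum(axis=0) / total
    return LagContribution(percent=percent, channel_lag_map=s,
                           channel_labels=model.channel_labels)


def assess_significance(result: DecodingResult, n_comparisons: int = 1,
                        ) -> np.ndarray:
    """Bonferroni-corrected p-values of each fold's correlation.

    Each r is tested against the exact null of zero Pearson correlation via
    ``t = r sqrt((n-2)/(1-r^2))`` with ``n - 2`` degrees of freedom
    (two-sided), then multiplied by ``n_comparisons`` and capped at 1.
    Returns a (folds, n_outputs) array.
    """
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    n = result.test_sample_counts.astype(float)
    if np.any(n < 3):
        raise ValueError("need at least 3 test samples per fold")
    r = np.clip(result.fold_r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n[:, None] - 2) / np.clip(1 - r ** 2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=n[:, None] - 2)
    return np.minimum(1.0, p * n_comparisons)


# ---------------------------------------------------------------------------
# Convenience drivers
# ---------------------------------------------------------------------------

def fit_full(trials: TrialSet, n_synergies: int = 3) -> WienerModel:
    """Full-dataset synergy decoder (all trials standardized together).

    This is the model the channel ranking and lag contributions are defined
    on; it deliberately uses the whole dataset.
    """
    std, _ = standardize(trials)
    std = project(std, fit_synergies(std, retained=n_synergies))
    return fit_wiener(std, outputs="pcs")


def decode_recording(rec: Recording, config: PipelineConfig | None = None, *,
                     outputs: str = "pcs") -> tuple[DecodingResult, TrialSet]:
    """Preprocess a raw recording and cross-validate the decoder."""
    config = config or PipelineConfig()
    _, trials, _ = preprocess(rec, config)
    result = cross_validate(
        trials, folds=config.cv_folds, seed=config.seed, outputs=outputs,
        fold_safe=config.fold_safe, n_synergies=config.n_synergies,
    )
    return result, trials
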