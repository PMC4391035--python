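"""Discrete five-class grasp classification and the information timeline.

A 100 ms window of preprocessed EEG — one lag-embedded sample, i.e. the
same (channel, lag) features the continuous decoder uses — is classified
into the five grasp types with a multiple-kernel SVM. The scalp is
partitioned into 8 regions of interest (ROIs); each ROI contributes RBF
basis kernels at relative widths sigma = {5, 10, 15}, 24 kernels in all,
combined as ``K = sum_m d_m K_m`` with simplex-constrained weights
(``d_m >= 0``, ``sum d_m = 1``).

The weights are learned by the SimpleMKL scheme: alternate between solving
the single-kernel SVM dual at fixed ``d`` and taking a reduced-gradient
descent step on ``d`` within the simplex, until the objective stops
decreasing. Multiclass uses one-vs-rest with per-binary kernel weights.

Classifier quality over time is summarized as mutual information between
measured and predicted grasp type, computed from the pooled cross-validated
confusion matrix, on a timeline from -1 to 3 s around movement onset in
250 ms steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import pairwise_distances
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

from .io_core import OBJECTS, PipelineConfig
from .preprocessing import TrialSet

logger = logging.getLogger(__name__)

__all__ = [
    "ROIMap",
    "default_roi_map",
    "KernelSet",
    "MKLClassifier",
    "build_kernels",
    "train_simplemkl",
    "window_features",
    "classify_windows",
    "ConfusionMatrix",
    "information_content",
    "InformationTimeline",
    "information_timeline",
    "permuted_label_accuracy",
]

#: Default 8-region partition of the retained 10-20 montage. Midline
#: channels (Fz, Cz, Pz, Oz, CPz, POz) belong to no lateralized region and
#: are left out of the kernel features; the map is user-overridable.
_DEFAULT_ROIS: dict[str, tuple[str, ...]] = {
    "LF": ("Fp1", "AF7", "AF3", "F7", "F5", "F3", "F1"),
    "RF": ("Fp2", "AF8", "AF4", "F8", "F6", "F4", "F2"),
    "LT": ("FT7", "T7", "TP7"),
    "RT": ("FT8", "T8", "TP8"),
    "LSM": ("FC5", "FC3", "FC1", "C5", "C3", "C1", "CP5", "CP3", "CP1"),
    "RSM": ("FC6", "FC4", "FC2", "C6", "C4", "C2", "CP6", "CP4", "CP2"),
    "LPO": ("P7", "P5", "P3", "P1", "PO7", "PO3", "O1"),
    "RPO": ("P8", "P6", "P4", "P2", "PO8", "PO4", "O2"),
}


@dataclass
class ROIMap:
    """Named scalp regions mapped to disjoint channel-label sets."""

    regions: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, chans in self.regions.items():
            chans = tuple(chans)
            if not chans:
                raise ValueError(f"ROI {name!r} is empty")
            overlap = seen & set(chans)
            if overlap:
                raise ValueError(f"ROIs overlap on {sorted(overlap)}")
            seen |= set(chans)
            self.regions[name] = chans

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.regions)


def default_roi_map(channel_labels) -> ROIMap:
    """The default 8-ROI partition, restricted to the available channels."""
    available = set(channel_labels)
    regions = {}
    for name, chans in _DEFAULT_ROIS.items():
        kept = tuple(ch for ch in chans if ch in available)
        if kept:
            regions[name] = kept
    if not regions:
        raise ValueError("no ROI channel present in the montage")
    return ROIMap(regions=regions)


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

@dataclass
class _KernelDef:
    roi: str
    sigma: float
    cols: np.ndarray      # feature-column indices of this ROI
    scale: float          # data-derived width scale s_m (median pairwise dist)


@dataclass
class KernelSet:
    """ROI x sigma basis kernels evaluated on a training sample set."""

    defs: list[_KernelDef]
    K: np.ndarray                     # (M, n_train, n_train)
    x_train: np.ndarray               # (n_train, n_features)

    @property
    def M(self) -> int:
        return len(self.defs)

    def cross(self, x: np.ndarray) -> np.ndarray:
        """Basis kernels between new samples and the training set:
        (M, n_new, n_train), using the training width scales."""
        out = np.empty((self.M, x.shape[0], self.x_train.shape[0]))
        for m, kd in enumerate(self.defs):
            d = pairwise_distances(x[:, kd.cols], self.x_train[:, kd.cols])
            out[m] = np.exp(-(d ** 2) / (2.0 * (kd.sigma * kd.scale) ** 2))
        return out


def _roi_columns(roi_channels, channel_labels, n_lags: int) -> np.ndarray:
    idx = [channel_labels.index(ch) for ch in roi_channels]
    return np.concatenate([np.arange(c * n_lags, (c + 1) * n_lags) for c in idx])


def build_kernels(features: np.ndarray, roi_map: ROIMap, sigmas,
                  channel_labels, n_lags: int) -> KernelSet:
    """RBF basis kernels per (ROI, sigma) on the training features.

    Each ROI's feature block is its channels x lags, flattened. The kernel
    is ``exp(-||xi - xj||^2 / (2 (sigma * s)^2))`` with
    ``s = median pairwise distance / sqrt(d)`` over the ROI's ``d`` feature
    dimensions on the training set — a dimension-free data scale, so the
    "relative" widths 5/10/15 span under- to over-smoothed kernels for
    typical ROI sizes regardless of channel count.
    """
    features = np.asarray(features, dtype=float)
    if features.shape[0] < 2:
        raise ValueError("need at least 2 samples to build kernels")
    unknown = {c for chans in roi_map.regions.values() for c in chans} \
        - set(channel_labels)
    if unknown:
        raise ValueError(f"ROI channels not among features: {sorted(unknown)}")
    defs: list[_KernelDef] = []
    mats: list[np.ndarray] = []
    for roi, chans in roi_map.regions.items():
        cols = _roi_columns(chans, channel_labels, n_lags)
        d = pairwise_distances(features[:, cols])
        iu = np.triu_indices_from(d, k=1)
        scale = float(np.median(d[iu])) / np.sqrt(len(cols))
        if scale == 0.0:
            logger.warning("ROI %s: zero median pairwise distance; "
                           "flooring scale at machine epsilon", roi)
            scale = float(np.finfo(float).eps)
        for sigma in sigmas:
            defs.append(_KernelDef(roi=roi, sigma=float(sigma), cols=cols,
                                   scale=scale))
            mats.append(np.exp(-(d ** 2) / (2.0 * (float(sigma) * scale) ** 2)))
    return KernelSet(defs=defs, K=np.stack(mats), x_train=features)


# ---------------------------------------------------------------------------
# SimpleMKL
# ---------------------------------------------------------------------------

@dataclass
class _BinarySolution:
    d: np.ndarray                    # (M,) simplex weights
    alpha_y: np.ndarray              # (n_train,) signed dual coefficients
    intercept: float
    objective: float
    objective_path: list[float] = field(default_factory=list)


def _solve_svm(kc: np.ndarray, y: np.ndarray, cost: float):
    """Single-kernel SVM dual via libsvm on a precomputed kernel.

    Returns (signed dual coefficients over all samples, intercept,
    dual objective value)."""
    try:
        svc = SVC(C=cost, kernel="precomputed").fit(kc, y)
    except ValueError:
        # numerically non-PSD combination: add jitter and retry
        logger.warning("combined kernel not PSD; adding diagonal jitter")
        svc = SVC(C=cost, kernel="precomputed").fit(
            kc + 1e-8 * np.eye(len(y)), y)
    alpha_y = np.zeros(len(y))
    alpha_y[svc.support_] = svc.dual_coef_[0]
    obj = float(np.abs(alpha_y).sum() - 0.5 * alpha_y @ kc @ alpha_y)
    return alpha_y, float(svc.intercept_[0]), obj


def _fit_binary_mkl(K: np.ndarray, y: np.ndarray, cost: float,
                    tol: float = 1e-3, max_outer: int = 40) -> _BinarySolution:
    """Reduced-gradient SimpleMKL for one binary problem.

    Alternates the SVM dual solve (fixed d) with a descent step on d along
    the reduced gradient within the simplex, accepting only steps that
    decrease the objective; terminates when the relative decrease falls
    below ``tol`` or the direction vanishes.
    """
    m = K.shape[0]
    d = np.full(m, 1.0 / m)

    def combined(dv):
        return np.tensordot(dv, K, axes=1)

    alpha_y, b, obj = _solve_svm(combined(d), y, cost)
    path = [obj]
    for _ in range(max_outer):
        grad = np.array([-0.5 * alpha_y @ K[i] @ alpha_y for i in range(m)])
        mu = int(np.argmax(d))
        reduced = grad - grad[mu]
        reduced[(d <= 0) & (reduced > 0)] = 0.0
        direction = -reduced
        direction[mu] = -(np.sum(direction) - direction[mu])
        if np.max(np.abs(direction)) < 1e-12:
            break
        with np.errstate(divide="ignore"):
            neg = direction < 0
            gamma_max = float(np.min(-d[neg] / direction[neg])) if np.any(neg) else 1.0
        if gamma_max <= 0:
            break
        improved = False
        gamma = gamma_max
        for _ in range(12):
            d_new = np.clip(d + gamma * direction, 0.0, None)
            d_new /= d_new.sum()
            a_new, b_new, obj_new = _solve_svm(combined(d_new), y, cost)
            if obj_new < obj:
                rel_drop = (obj - obj_new) / max(abs(obj), 1e-12)
                d, alpha_y, b, obj = d_new, a_new, b_new, obj_new
                path.append(obj)
                improved = True
                if rel_drop < tol:
                    return _BinarySolution(d, alpha_y, b, obj, path)
                break
            gamma *= 0.5
        if not improved:
            break
    else:
        logger.warning("SimpleMKL did not converge in %d outer iterations; "
                       "returning best iterate", max_outer)
    return _BinarySolution(d, alpha_y, b, obj, path)


@dataclass
class MKLClassifier:
    """One-vs-rest multiple-kernel SVM with per-binary simplex weights."""

    classes: tuple[str, ...]
    binaries: list[_BinarySolution]
    kernels: KernelSet

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        """(n_samples, n_classes) one-vs-rest decision values."""
        basis = self.kernels.cross(np.asarray(x, dtype=float))
        out = np.empty((x.shape[0], len(self.classes)))
        for c, sol in enumerate(self.binaries):
            kc = np.tensordot(sol.d, basis, axes=1)
            out[:, c] = kc @ sol.alpha_y + sol.intercept
        return out

    def predict(self, x: np.ndarray) -> np.ndarray:
        scores = self.decision_function(x)
        return np.asarray(self.classes, dtype=object)[np.argmax(scores, axis=1)]


def train_simplemkl(kernels: KernelSet, labels, cost: float = 1.0,
                    tol: float = 1e-3, max_outer: int = 40) -> MKLClassifier:
    """Fit the one-vs-rest SimpleMKL classifier on precomputed basis kernels."""
    labels = np.asarray(labels, dtype=object)
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train a classifier")
    binaries = []
    for cls in classes:
        y = np.where(labels == cls, 1.0, -1.0)
        binaries.append(_fit_binary_mkl(kernels.K, y, cost, tol, max_outer))
    return MKLClassifier(classes=classes, binaries=binaries, kernels=kernels)


# ---------------------------------------------------------------------------
# Windows, confusion matrices, information
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """Counts with rows = measured grasp, columns = predicted grasp."""

    counts: np.ndarray                # (K, K) non-negative integers
    classes: tuple[str, ...]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total


def window_features(trials: TrialSet, time_ms: float,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract the lag-embedded EEG sample at onset + ``time_ms`` per trial.

    Returns (features, labels, kept trial indices); trials whose segment
    does not contain the window are skipped with a log entry. Each feature
    row is the (channels x lags) matrix at that instant, flattened — by
    construction a 100 ms history window of every channel.
    """
    rows, labs, kept = [], [], []
    offset = time_ms / 1000.0 * trials.fs
    for i, e in enumerate(trials.eeg):
        idx = int(round(offset)) - trials.start_offset[i]
        if 0 <= idx < e.shape[0]:
            rows.append(e[idx].reshape(-1))
            labs.append(trials.labels[i])
            kept.append(i)
    n_skip = trials.n_trials - len(kept)
    if n_skip:
        logger.info("window at %+d ms: %d trials lack the window; skipped",
                    int(time_ms), n_skip)
    if not rows:
        return (np.empty((0, trials.n_channels * (trials.L + 1))),
                np.empty(0, dtype=object), np.empty(0, dtype=int))
    return np.vstack(rows), np.asarray(labs, dtype=object), np.asarray(kept)


def _standardize_rows(train: np.ndarray, test: np.ndarray):
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mean) / sd, (test - mean) / sd


def classify_windows(trials: TrialSet, time_ms: float,
                     roi_map: ROIMap | None = None,
                     config: PipelineConfig | None = None,
                     class_order: tuple[str, ...] | None = None,
                     ) -> ConfusionMatrix:
    """Cross-validated grasp classification of one 100 ms EEG window.

    Features are standardized per (channel, lag) column with training-fold
    statistics, matching the decoder's feature conditioning; kernels and
    their width scales are likewise fitted on the training fold only. The
    confusion matrix pools counts over all test folds. Classes absent at
    this time point keep their (zero) row.
    """
    config = config or PipelineConfig()
    roi_map = roi_map or default_roi_map(trials.channel_labels)
    if class_order is None:
        class_order = tuple(o for o in OBJECTS if o in set(trials.labels)) \
            or tuple(sorted(set(trials.labels)))
    x, y, _ = window_features(trials, time_ms)
    if x.shape[0] < config.cv_folds:
        raise ValueError(
            f"only {x.shape[0]} trials contain the window at {time_ms} ms")
    class_idx = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    present = np.unique(y)
    if len(present) < 2:
        raise ValueError("fewer than 2 classes present at this time point")
    min_count = min(np.sum(y == c) for c in present)
    if min_count >= config.cv_folds:
        splitter = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                                   random_state=config.seed)
    else:
        logger.warning("classes too sparse to stratify; plain K-fold")
        splitter = KFold(n_splits=config.cv_folds, shuffle=True,
                         random_state=config.seed)
    for tr, te in splitter.split(x, y):
        if len(np.unique(y[tr])) < 2:
            logger.warning("training fold with a single class; fold skipped")
            continue
        x_tr, x_te = _standardize_rows(x[tr], x[te])
        kernels = build_kernels(x_tr, roi_map, config.sigmas,
                                trials.channel_labels, trials.L + 1)
        clf = train_simplemkl(kernels, y[tr], cost=config.svm_cost)
        pred = clf.predict(x_te)
        for truth, guess in zip(y[te], pred):
            counts[class_idx[truth], class_idx[guess]] += 1
    return ConfusionMatrix(counts=counts, classes=class_order)


def information_content(cm: ConfusionMatrix) -> float:
    """Mutual information (bits) between measured and predicted grasp.

    ``I = sum_{PG,MG} P(PG,MG) log2[P(PG,MG) / (P(PG) P(MG))]`` with the
    joint taken from the normalized confusion counts and the convention
    ``0 log 0 = 0``; bounded by log2 of the class count.
    """
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    joint = cm.counts / total
    p_mg = joint.sum(axis=1, keepdims=True)
    p_pg = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (p_mg * p_pg))
    return float(np.nansum(terms))


@dataclass
class InformationTimeline:
    """Information (bits) about grasp type per classification time."""

    times_ms: np.ndarray
    info_bits: np.ndarray             # NaN where classification impossible
    confusions: list[ConfusionMatrix | None]
    n_trials: np.ndarray


def information_timeline(trials: TrialSet,
                         roi_map: ROIMap | None = None,
                         config: PipelineConfig | None = None,
                         times_ms=None) -> InformationTimeline:
    """Classify EEG windows from -1 to 3 s around onset in 250 ms steps.

    The trials must have been segmented with margins wide enough to contain
    the requested windows (the generator's inter-trial rest periods provide
    the pre-onset context); a trial lacking a given window skips that time
    point only. Raises if no time point has two classes to separate.
    """
    config = config or PipelineConfig()
    if times_ms is None:
        times_ms = np.arange(-1000, 3001, 250)
    times_ms = np.asarray(times_ms, dtype=float)
    info = np.full(len(times_ms), np.nan)
    confusions: list[ConfusionMatrix | None] = [None] * len(times_ms)
    n_kept = np.zeros(len(times_ms), dtype=int)
    for j, t in enumerate(times_ms):
        _, y, kept = window_features(trials, t)
        n_kept[j] = len(kept)
        try:
            cm = classify_windows(trials, t, roi_map=roi_map, config=config)
        except ValueError as exc:
            logger.warning("time %+d ms unclassifiable: %s", int(t), exc)
            continue
        confusions[j] = cm
        info[j] = information_content(cm)
    if np.all(np.isnan(info)):
        raise ValueError("no time point with at least 2 classes")
    return InformationTimeline(times_ms=times_ms, info_bits=info,
                               confusions=confusions, n_trials=n_kept)


def permuted_label_accuracy(trials: TrialSet, time_ms: float,
                            repetitions: int = 5, seed: int = 0,
                            roi_map: ROIMap | None = None,
                            config: PipelineConfig | None = None) -> np.ndarray:
    """Empirical chance accuracy: classification with shuffled labels.

    Returns one pooled-confusion accuracy per repetition; for balanced
    five-class data this hovers around 0.2.
    """
    import dataclasses as _dc
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(repetitions):
        perm = rng.permutation(trials.n_trials)
        shuffled = _dc.replace(trials,
                               labels=[trials.labels[i] for i in perm])
        cm = classify_windows(shuffled, time_ms, roi_map=roi_map, config=config)
        out.append(cm.accuracy)
    return np.asarray(out)
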