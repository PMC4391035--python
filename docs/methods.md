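# Methods

## Problem and model

`graspdecode` implements an offline analysis that infers hand-grasp
kinematics from low-frequency scalp EEG recorded while a subject performs
natural reach-to-grasp movements to one of five objects (can, card, CD,
penny, screwdriver). Two questions are addressed: can continuous joint
angular velocities — or their low-dimensional synergies — be decoded from
the time-domain amplitude of 0.1–1 Hz EEG, and how much information about
the discrete grasp type do short EEG windows carry over the course of a
movement?

### Continuous decoding

Joint angular velocities of 15 hand joints (finger MCP/PIP, thumb
CMC/MCP/IP, four abduction joints) are decomposed by PCA into kinematic
synergies; the first three components are retained. A Wiener filter — an
affine lagged linear model — predicts each synergy trajectory from the
preprocessed EEG:

    PC_i[t] = b0_i + sum_{n=1..N} sum_{k=0..L} beta_nki * EEG_n[t − k]

with N = 58 channels and L + 1 = 11 lags covering 0–100 ms of history in
10 ms steps. Coefficients are fitted by ordinary least squares (normal
equations on the flattened channel × lag design; a rank-deficient design
falls back to the minimum-norm solution). Accuracy is the median across
8 stratified cross-validation folds of the Pearson correlation between
predicted and observed output samples, concatenated within each test fold.

Channel relevance is summarized as R_n, the mean over lags of the
root-sum-square of the three synergy coefficients from a full-dataset fit;
accuracy-vs-channel-count curves decode with the best N channels
(N = 1..58) and locate the peak with a multi-start double-exponential fit
a·e^{bN} + c·e^{dN} (integer argmax of the fit). Per-lag contributions
%T_k normalize the channel-summed coefficient magnitude per lag to 100%.
Per-fold correlations are tested against the exact Pearson null
(t = r·sqrt((n−2)/(1−r²)), two-sided) with Bonferroni correction.

### Preprocessing

EEG: linear detrend, zero-phase 4th-order Butterworth high-pass at
0.3 Hz, optional spatial-projection hook (artifact subspace removal),
zero-phase 4th-order low-pass at 1 Hz, decimation to 100 Hz (the low-pass
is the anti-alias filter), first-difference differentiation scaled by the
sampling rate. Kinematics: identical low-pass / decimate / differentiate
chain, with the low-pass distortion quantified by the signal-to-error
ratio SER = 10·log10(Var(y)/MSE(y, y*)). Trials span 400 ms before
movement onset to 100 ms after offset; the pre-onset margin always covers
the 100 ms lag history, so no trial touches samples without full context.
Each (channel, lag) feature is standardized to zero mean / unit SD.

Two leakage policies are provided. The *fold-safe* default computes
standardization statistics and the synergy PCA on the training folds only
and applies them to held-out trials. The alternative computes both across
all trials before cross-validation — faithful to the original analysis
but mildly optimistic; it is kept available via configuration
(`fold_safe: false`) because reproducing that choice is itself of
interest.

### Surrogate chance levels

Two surrogates destroy the EEG–kinematics association while preserving
marginal signal statistics: *phase scrambling* (per-channel Fourier phases
randomized with conjugate symmetry, magnitudes — hence autocovariances —
preserved exactly) applied to the continuous band-limited EEG before lag
embedding, and *fold scrambling* (EEG permuted across trials by a uniform
cyclic permutation, which is always a derangement, while kinematics and
labels stay in place; mismatched lengths truncated to the shorter).
Phases are drawn independently per channel. The full cross-validated
decoding is re-run on each surrogate, five repetitions per method, with
per-repetition seeds logged; the chance level is the pooled mean ± SEM of
the median-r metric.

### Discrete classification

A 100 ms EEG window — one lag-embedded sample, i.e. the same
channel × lag features as the decoder — is classified into the five grasp
types with a multiple-kernel SVM. The scalp is partitioned into 8 regions
(left/right frontal, temporal, sensorimotor, parieto-occipital); each
region contributes RBF kernels at relative widths σ ∈ {5, 10, 15}, 24
basis kernels in all, combined as K = Σ d_m K_m with d on the simplex.
"Relative" width is interpreted against a dimension-free data scale: the
kernel width is σ·s with s the median pairwise training distance within
the region's feature block divided by the square root of its dimension,
so that for typical ROI sizes (30–100 features) the three widths span
roughly 0.5–1.6× the median distance — from sharply local to
over-smoothed kernels — independent of channel count. The width scale is
always estimated on the training fold. Weights are optimized by SimpleMKL: alternating the single-kernel
SVM dual solve (via libsvm on the precomputed combined kernel) with a
reduced-gradient descent step on d inside the simplex, accepting only
objective decreases, until the relative decrease falls below 1e-3.
Multiclass uses one-vs-rest with per-binary kernel weights and argmax of
decision values; the SVM cost defaults to C = 1.

Classifier quality is summarized as the mutual information between
measured and predicted grasp computed from the pooled cross-validated
confusion matrix, I = Σ P(PG,MG) log2[P(PG,MG)/(P(PG)P(MG))], on a
timeline from −1 to 3 s around movement onset in 250 ms steps. Window
features are standardized per column with training-fold statistics,
mirroring the decoder's conditioning. Note the plugin information
estimate carries a small-sample bias of roughly (K−1)²/(2·n·ln 2) bits,
so near-zero information reads as ≈ 0.05 bits at n = 250.

## Synthetic data

No recordings are distributed with the analysis, so a generator produces
EEG/kinematics pairs with the statistical structure the method assumes,
at the study's scale: 64-channel EEG at 1000 Hz (10-20 montage with
mastoids), 15 joints, 5 objects × 50 trials, movement time 1.9 ± 0.3 s,
1–2 s inter-trial rests.

Each trial draws per-object synergy velocity profiles (opposing Gaussian
bump pairs — opening and closing — with object-specific amplitudes,
timing offsets and bump widths; the three components use distinct
open/close timings so their time courses are only weakly correlated and
PCA can separate them). On top of the object profile, each trial adds
smooth trial-idiosyncratic motor variability in synergy space (85% of
within-trial variance, 80 ms smoothness, zero net displacement). This
idiosyncrasy is essential realism: single-trial grasps are not
stereotyped, and without it a decoder refit on scrambled EEG–kinematics
pairings would still learn the onset-locked common-mode trajectory and
"decode" far above zero — contradicting the near-zero scrambled chance
levels the method is expected to show. Because the idiosyncratic
component is shared by EEG and kinematics through the coupling, true-pair
decodability is unaffected.

Joint velocities are a fixed orthonormal 15 × 3 loading matrix (aperture,
spread, thumb) applied to the synergy velocities plus small sensor noise
(0.5 deg/s); angles are their cumulative integral. EEG amplitude on 8
informative left sensorimotor/parietal channels is a causally *leading*
lagged mixture of the position-domain (integrated) synergy trajectories,
with coupling concentrated at 40–100 ms lags on a 10 ms grid. Coupling in
the position domain is deliberate: the processing chain differentiates
EEG, so position-domain coupling makes the processed EEG a lagged linear
function of the velocity-domain synergies the decoder targets, whereas
velocity-domain coupling would leave a 90° phase mismatch no 100 ms lag
filter could absorb.

Noise is white plus 1/f (spectrally shaped), scaled per channel so the
coupling-signal to noise variance ratio within 0.1–1 Hz — the only band
surviving preprocessing — equals the requested SNR (default 10) on
informative channels; non-informative channels receive the mean noise
scale. An optional ocular artifact (fronto-polar topography × detrended
random-walk time course) is off by default and used only in
artifact-robustness tests. Identical seeds give byte-identical output,
and an SNR sweep changes only the noise scaling.

What the generator does **not** emulate: volume-conducted correlations
between channels, non-stationary background rhythms (alpha/mu), EMG
artifacts, electrode drift or pops, behavioral error trials, and any
nonlinearity in the EEG–kinematics relation. Passing tests therefore show
the pipeline recovers the structures it assumes, at realistic sizes and
noise levels — not that real EEG carries this structure.

## Numerical choices

- OLS via normal equations with a minimum-norm (truncated SVD) solve of
  the Gram system; 10 ms-spaced lags of 1 Hz-limited signals are nearly
  collinear, so effective rank deficiency is expected and logged. Tests
  cross-check against the SVD pseudoinverse of the design matrix.
- Pearson r over concatenated test samples per fold; zero-variance
  predictions record r = 0 with a warning.
- Stratified, seeded fold assignment at the trial level; plain K-fold
  fallback (with warning) when a class has fewer trials than folds.
- Double-exponential fits run 8 seeded starts spanning sign patterns;
  non-convergence falls back to the raw-curve argmax with a warning.
- Standardization treats features with sd below 100·eps·max(1, |mean|)
  as dead (left at zero with a warning).
- Phase scrambling leaves DC and (even length) Nyquist bins untouched so
  the output is exactly real.
- SimpleMKL adds 1e-8 diagonal jitter if the combined kernel is
  numerically non-PSD; a zero median pairwise distance floors the kernel
  width scale at machine epsilon.
- Sample indexing is 0-based with half-open intervals; trial segments
  include one sample beyond the stated end margin (onset−400 ms …
  offset+100 ms inclusive).

## Problem sizes

Unit tests run a reduced configuration (24–64 channels, 8–10 trials per
object, 200 Hz) chosen so the whole suite exercises every stage in a few
minutes; the acceptance tests and `scripts/acceptance.py` regenerate the
full study scale (64 channels at 1000 Hz, 250 trials, SNR 10) and run the
complete pipeline, including both surrogate suites at 5 repetitions each,
on it.

## Known limitations

- Interactive independent-component artifact removal is replaced by a
  spatial-projection hook; selecting eye components automatically is out
  of scope.
- The exact region-of-interest channel assignment and the vendor marker
  scheme are user configuration (sane defaults ship for the 64-channel
  montage; marker semantics are never guessed).
- The paper-faithful leakage policy (global standardization/PCA) slightly
  overstates accuracy; the fold-safe default is the honest estimate.
- Median-of-folds correlation has no analytic null here; chance levels
  are always empirical (surrogates).
- The synthetic five-class accuracy and information values depend on the
  generator's motor-variability and SNR settings and are not comparable
  to any particular human dataset.
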