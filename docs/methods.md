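# Methods

This note records the modelling choices, numerical conventions and known
limitations behind the pipeline. Everything stated here is computed by
the test suite or by `scripts/acceptance.py`; nothing is quoted from
external runs.

## Segments and feature layout

A trial is a `channels × samples` matrix with sampling rate, unique
channel labels and a class label. The default configuration targets the
common MI recording format: 22 channels, 250 Hz, 3-second trials
(750 samples). Feature columns are laid out channel-major with family
order time → fft → wpd → poincare, so the layout is a pure function of
the channel labels and the configuration; with the defaults the count is
22 × (24 + 15 + 15 + 8) = 1,364. Feature tables are CSV with a header of
feature names and a trailing `label` column, written at 17 significant
digits so round-trips are lossless at double precision.

## Time-domain features

The 24 descriptors use these conventions:

* SD/variance and all other sample variances use the n−1 denominator.
  Kurtosis is non-excess (a normal distribution scores 3) and, like
  skewness, uses the biased moment estimator — the default of the
  numerical environments these features historically come from.
* IEEG = Σ|x|, MAV = IEEG/N, SSI = Σx², RMS = √(SSI/N),
  WL = Σ|Δx|, AAC = WL/(N−1), DASDV = √(Σ(Δx)²/(N−1)) — the standard
  EMG/EEG definitions. "Absolute difference in standard deviation" is
  read as DASDV (the SD of successive differences), the usual expansion
  of that name in the feature literature.
* Mode: amplitudes are rounded to 2 decimals first (a continuous signal
  has no repeated values); ties break toward the smallest value.
* Quartiles interpolate linearly between order statistics; Q2 is the
  median.
* Zero crossings count strict sign products `x_i·x_{i+1} < 0` (exact
  zeros do not count); slope-sign changes count
  `(x_i−x_{i−1})(x_{i+1}−x_i) < 0`; no amplitude threshold.
* Hjorth derivatives are first differences without fs scaling — mobility
  and complexity are ratios, so the sampling interval cancels. A
  zero-variance signal returns (0, 0, 0); at N = 3 the single second
  difference cannot support a sample variance, so complexity is 0.

## FFT subband features

Bins of the one-sided DFT (0-based, bin k ↔ k·fs/N Hz) belong to a band
on the half-open rule `low ≤ f < high`, so adjacent bands never share a
bin and at fs = 250, N = 750 the five default bands exactly partition
[0.5, 100) Hz. Energy sums squared magnitudes; variance is the sample
variance of the in-band magnitudes (a real-valued reduction of the
complex spectrum); entropy is normalised Shannon entropy of the in-band
power weights, natural log, scaled by 1/log M to [0, 1]. Bands whose
energy is at floating-point-residue level relative to total spectral
power (≤ 1e−24 of it) report entropy 0 — a numerically constant signal
has no band structure. No taper is applied by default (a Hann option
exists); spectral leakage across band edges is accepted as part of the
feature definition.

A note on calibration of the entropy: for a flat (white-noise) spectrum
the power-weighted entropy of M iid exponential bin powers has
expectation ≈ 1 − (1−γ_E)/log M, i.e. ~0.84 for the 15-bin alpha band
and > 0.9 only for wide bands such as gamma (210 bins). The tests assert
exactly this, not a uniform "near 1".

## Wavelet-packet subband features

The full Haar packet tree is taken to level 7, with periodic boundary
handling, giving 128 terminal nodes of width fs/2⁸ ≈ 0.977 Hz after
remapping the tree's natural (Paley) order to frequency order — without
that remap every band above level 1 would collect the wrong nodes.
Signals are zero-padded to the next multiple of 2⁷; with Haar filters
and periodic extension the padding contributes only zero coefficients
and the transform stays orthonormal (total coefficient energy equals
Σx², verified to 1e−6 relative).

A node belongs to the band containing its centre frequency
(n + 0.5)·fs/2⁸. One deliberate exception: the DC node (centre
~0.49 Hz, just below delta's 0.5 Hz edge) joins the lowest band whenever
the band's lower edge falls inside the node's span — the node carries
the segment mean and slow drift, which belong with the slowest rhythm
rather than nowhere. Nodes between 100 and 125 Hz fall outside every
default band and are discarded. Pooled per-band coefficients yield
energy, Shannon entropy of normalised coefficient energies (the sign and
normalisation that make an entropy well-defined; the literal
unnormalised `Σc² log c²` form is available behind
`wavelet_literal_entropy` for comparison), and sample variance. A plain
DWT mapping (detail level i ↔ [fs/2^{i+1}, fs/2^i)) is available behind
`wavelet_transform="dwt"`.

## Poincaré descriptors

SD1/SD2 are sample SDs (n−1) over the rotated lagged pairs, computed on
raw amplitudes, with lags 1 and 9 by default. SD2 = 0 (e.g. a constant
segment) makes the ratio 0 rather than NaN/∞ so feature matrices stay
finite. Preconditions require lag + 3 samples (three plot points).

## Significance screening

Two classes → Student's pooled-variance t-test (Welch behind a flag);
three or more → one-way fixed-effects ANOVA. Degenerate columns with
zero variance in every group score p = 1 when group means agree and
p = 0 when they differ. Selection keeps p < α strictly, α = 0.05, with
no multiple-testing correction by default — a faithful-replication
choice; `correction="bh"` provides Benjamini–Hochberg as a clearly
marked extension. By default the screen runs on the full dataset before
cross-validation, replicating the reference sequence; this leaks label
information across folds, so a leakage-free mode
(`leakage_free_selection`, refitting the screen inside every training
fold) is provided as the methodologically safer alternative.

## Classification bench

Presets approximate the conventional fine/medium/coarse graduations:
tree leaf budgets 100/20/4; k-NN k = 1/10/100 Euclidean, plus cosine,
Minkowski-3 ("cubic") and inverse-squared-distance-weighted k = 10; SVM
box constraint 1 with linear, polynomial (2, 3) and RBF kernels at
kernel scales √p/4, √p, 4√p; Gaussian and kernel-density Naive Bayes
(per-feature Gaussian KDE, Silverman bandwidth); logistic regression
(two classes only); bagged trees, SAMME-boosted trees, random-subspace
k-NN and discriminant ensembles (30 learners, subspace ⌈p/2⌉), and a
RUSBoost variant that undersamples every class to the smallest class
before each boosting round. k-NN, SVM and logistic regression are
standardised with train-fold mean/SD; tree and discriminant families run
on raw features. Discriminant fits use diagonal-loading shrinkage so
singular within-class covariances (p ≥ n is routine at 1,364 features)
degrade gracefully instead of crashing.

The random-subspace discriminant ensemble — the pipeline's headline
classifier — is implemented from scratch: feature subsets drawn without
replacement per learner from a seeded generator, posteriors averaged,
ties broken toward the lowest class index. `n_learners=1` with the full
feature set reproduces a plain regularised LDA exactly (tested).

Cross-validation is stratified k-fold (default k = 5), re-randomised
each repeat (default 10) from (seed, repeat); all aggregate metrics are
means over folds and repeats. Whether the reference analysis stratified
its folds or standardised features is unstated; both choices here are
recorded in the pipeline report's assumptions block.

## Synthetic generator

Each channel of a segment is 1/f^γ background noise (γ = 1, RMS 2) plus
five band-limited oscillations built by spectrally filtering white noise
— filtered-noise synthesis, chosen so each band has realistic in-band
variance for the variance/entropy features. Baseline band amplitudes
(δ 1.5, θ 1.0, α 2.0, β 1.0, γ 0.4 in arbitrary units) follow the usual
resting-spectrum shape with alpha dominant; each amplitude gets
lognormal trial-to-trial jitter (SD 0.1 in log space). The class effect
is amplitude-only: on each class's designated channels (disjoint
3-channel blocks by default) the affected band's amplitude — alpha by
default — is scaled by (1 − effect_size), mimicking
event-related desynchronisation. `effect_size=0` is the null mode.
Randomness comes from a per-segment substream seeded by
(seed, segment index), so datasets are bit-reproducible.

What the generator does not emulate: volume conduction and channel
covariance, phase/latency effects, artifacts (blinks, EMG), 50 Hz line
noise, non-stationarity within a trial, and between-subject variability.
Passing tests therefore demonstrate that the pipeline recovers
band-power class structure it is designed for — not that the
classifiers' accuracy rankings would transfer to real recordings, where
effects are far weaker and noisier. With the default amplitudes, even
moderate effect sizes are near-perfectly separable at tens of trials per
class; the calibration tests rely on the null mode instead.

## Problem sizes in the validation runs

The statistical checks run at: null calibration — 4 classes × 25
segments/class, with the selected-feature fraction averaged over four
replicate datasets (features within a segment are correlated, so a
single dataset's fraction has roughly ±1.5 % spread where independent
features would give ±0.6 %; averaging replicates restores the intended
precision around the nominal 5 %); chance-level CV — the same 100
segments, 5-fold, subspace discriminant, compared against 25 % with a
3-SD binomial band; signal recovery — 2 classes × 100 segments/class at
effect size 0.9, requiring every injected alpha-energy feature retained
and ≥ 90 % 5-fold accuracy. These sizes were chosen as the smallest at
which the binomial tolerances quoted above are meaningful.

## Known limitations

* EDF loading goes through `mne` (an optional extra); the original
  competition GDF files are out of scope.
* Eq-level agreement with any particular commercial implementation of
  the classifier presets is approximate by design; presets fix
  hyperparameters, not internals.
* The spectral variance feature reduces complex DFT coefficients to
  magnitudes before taking a variance; other reductions (real/imaginary
  parts, power) would give different but equally defensible features.
* 100–125 Hz wavelet content is discarded rather than folded into gamma.
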