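# Methods

This note records the scientific and numerical choices behind `mibci`: the
signal model, the feature definitions, the selection and evaluation
procedures, what the synthetic generator emulates, and the decisions taken
where the design was genuinely open.

## Signal model and preprocessing

The unit of classification is a cue-locked epoch of multichannel EEG
recorded during binary motor imagery. The discriminative physiology is
event-related desynchronization: the amplitude of the sensorimotor μ
(8–13 Hz) and β (13–30 Hz) rhythms drops over the hemisphere contralateral
to the imagined limb.

Preprocessing runs in a fixed order on the *continuous* recording:

1. **Band-pass 10–30 Hz**, 5th-order Butterworth, designed as second-order
   sections and applied forward–backward (`sosfiltfilt`). Zero-phase
   application is essential: a causal filter would delay the signal
   relative to the cue markers and shift every epoch. The effective
   magnitude response is the square of the single-pass response; the
   pass-band checks in the tests account for that.
2. **Per-channel z-scoring** with the population (divide-by-N) standard
   deviation over the full recording, consistent with the population
   moments used everywhere else in the feature set. Normalizing before
   epoching means epoch statistics remain comparable across channels and
   sessions. A constant channel is an error, not a silent NaN.
3. **Notch at 60 Hz** (second-order IIR, quality 30, zero-phase), optional
   because some acquisition systems deliver pre-notched data. The
   composed `preprocess` chain skips the stage with a warning when the
   configured line frequency is at or above Nyquist — data sampled below
   2×60 Hz cannot carry that interference — while the standalone
   `notch_filter` keeps its strict parameter contract.
4. **Epoching** with half-open, 0-based sample windows
   `[round((cue+start)·fs), round((cue+end)·fs))`, so every trial has
   exactly `round((end−start)·fs)` samples at any sampling rate.

No artifact rejection (EOG/EMG regression, ICA) is performed; the filters
are the only cleaning stages.

## Feature sets

**Time domain, 6 per channel** — RMS, Rényi entropy, Hjorth mobility and
complexity, waveform length, mean absolute value, computed on the
band-passed normalized epoch. Two definitions deserve note:

* *Rényi entropy* is defined on probability distributions, so the epoch is
  first mapped to its normalized energy distribution
  `p_j = y_j²/Σy²`; `H_q = log(Σ p_j^q)/(1−q)` (natural log) then lies in
  `[0, log M]`. Applying the power sum to raw, possibly negative samples
  would be ill-defined for non-integer q. The order defaults to q = 2
  (quadratic Rényi, the standard EEG choice) and is configurable.
* *Hjorth derivatives* are plain first differences, not scaled by fs. The
  scale factor cancels exactly in complexity and multiplies mobility by a
  constant shared across all trials, which no downstream classifier or
  correlation can see.

Hjorth *activity* (the variance) is available behind the
`include_activity` flag but is off by default; the default layout is the
six-feature one, which is what makes the fused totals come out at 102
features per channel.

**Wavelet packets, 96 per channel** — a full 4-level wavelet-packet
decomposition (both approximation and detail branches split at every
level) yields 2⁴ = 16 terminal sub-bands, reordered frequency-ascending
(Gray-code reordering of the natural tree order) so that "adjacent
sub-bands" are physically adjacent in frequency. Per sub-band: absolute
mean μ, average power, population SD, adjacent-band ratio γ, and the
population skewness and non-excess kurtosis.

Open choices, and how they were fixed:

* *Wavelet family*: unspecified in the protocol this follows; db4 by
  default (standard in the EEG wavelet-packet literature), configurable.
* *Boundary handling*: periodization by default, because it makes the
  transform an orthonormal change of basis — coefficient count equals the
  signal length and energy is conserved, both verified in the tests
  against pywt's inverse transform. Other modes are configurable but lose
  the exact invariants.
* *γ layout*: n sub-bands have only n−1 physical adjacencies, which would
  give 95 wavelet columns per channel. The default closes the ring
  (γ_last = μ_last/μ_first) so every sub-band contributes one ratio and
  the per-channel total is exactly 6×16 = 96. The documented alternative —
  adjacent-only γ plus Hjorth activity in the time block — also sums to
  102 per channel and is selectable as
  `layout_variant="adjacent-gamma-plus-activity"`.

Fusion concatenates the time block first; fused width is
`channels × (6 + 6·2^level)`: 1836 columns for the 18-channel montage,
1326 for the 13-channel one.

## Hybrid feature selection

**CFS filter.** Subset merit is
`k·r̄_cf / √(k + k(k−1)·r̄_ff)` with r̄_cf the mean absolute
feature–class correlation (point-biserial, i.e. Pearson against the 0/1
label) and r̄_ff the mean absolute pairwise feature–feature Pearson
correlation. The search is best-first from the empty set with a patience
of 5 consecutive non-improving expansions (the canonical CFS default).
Correlations are precomputed once; candidate merits per expansion are
vectorized through cached subset sums, so the filter handles the
1836-column matrix in well under a second. Constant columns carry no
signal and are excluded from the search; ties break toward
lexicographically smaller subsets for determinism.

**Wrapper.** Greedy forward selection over the CFS survivors, scored by
stratified inner-CV accuracy (default 10 folds from a seeded shuffle; the
same folds score every candidate, so comparisons are paired). Only strict
improvements are accepted (ties to the lowest column index), and the
baseline is the majority-class rate, so the accepted-accuracy trace is
strictly increasing and termination is guaranteed. The wrapper classifier
defaults to the same spec used for final evaluation.

All selectors are scikit-learn `SelectorMixin` estimators. Under
cross-validation the selector is *cloned and refit on each training fold*;
the leaky variant (select once on the full matrix) exists only behind an
explicit `leaky_fs` flag for comparison with unnested protocols, because
unnested selection optimistically biases reported accuracy.

## Classifiers and evaluation

Linear-kernel SVM (C = 1), LDA (least-squares solver with automatic
shrinkage — necessary because the fused feature count far exceeds the
trial count, making the within-class covariance singular), and KNN with
Euclidean distance and odd k = 5 (no vote ties). All constants are
config-exposed; results on the bundled fixtures are insensitive to them.

Evaluation is stratified 10-fold CV from a seeded shuffle (stratification
guards against single-class folds at small n). Each fold yields confusion
counts (TP, FN, TN, FP) from which accuracy, sensitivity, specificity,
precision and F1 are computed; a metric with a zero denominator is
reported as NaN, never silently 0. AUC uses continuous scores — the SVM
margin, the LDA posterior difference, or the KNN vote fraction — and
equals the Mann–Whitney pair-counting statistic (verified exhaustively in
the tests). The positive class is the lexicographically larger label
unless overridden, fixing the sensitivity/specificity orientation.

## Synthetic data: what it emulates, and what it does not

Each channel carries 1/f background noise (spectrally shaped white noise,
exponent 1, 10 µV RMS) plus band-limited μ and β oscillations built from
band-passed white noise (15 and 8 µV RMS — at central electrodes the
sensorimotor idling rhythm dominates its band). On the informative
channels the oscillation amplitude is scaled by (1 ± effect/2) per class,
lateralized: the first half of the informative channels is attenuated for
class A and amplified for class B, and vice versa. At the default
`effect = 1` the class amplitude ratio is 3, i.e. a 9× band-power
contrast; `effect = 0` is an exact null. An optional 60 Hz tone models
line pickup. Defaults: 100 trials per class, 18 channels at 100 Hz
(labels from the 18-channel sensorimotor montage; informative channels
default to C3 and C4), 4 s trials with 1 s gaps, everything reproducible
from one seed.

Oscillations are noise-driven rather than sinusoidal so wavelet-packet
sub-bands receive broadband structure, and trial-to-trial amplitude
variability arises naturally from the filtered noise. What the generator
does **not** model: volume conduction and channel covariance,
non-stationarity within trials, eye/muscle artifacts, subject variability,
or realistic single-trial SNR. The strong-effect fixture is deliberately
easy — a 9× power contrast — so passing it establishes that the pipeline
is *correct and leak-free*, not that it would reach any particular
accuracy on real recordings. The null fixture establishes the converse:
with no class signal, accuracy stays inside the binomial 95% interval of
chance, which would fail under selection leakage.

## Problem sizes and numerical choices

The bundled fixtures use 200 trials (100 per class) of 18 or 13 channels
at 100 Hz, giving 300-sample epochs under the default 0.5–3.5 s window —
sizes at which the full test suite and the acceptance script each run in
minutes on a single core. Epochs of 300 samples are not divisible by 16,
so coefficient-count/energy invariants are exact only on divisible lengths
(the tests use 256); feature values themselves are unaffected. EDF
round-trips are exact to the 16-bit quantization step (channel range /
2¹⁶); the matrix-bundle format round-trips losslessly via 17-significant-
digit text. The hand-written EDF writer targets fixture interchange:
uniform sampling rate, 1 s records, cue annotations; reading goes through
mne and accepts any EDF/EDF+ it can parse.

## Known limitations

* Binary tasks only; multiclass MI is out of scope.
* No artifact rejection beyond filtering; no online/streaming decoding.
* The wrapper's greedy, strictly-improving search can under-select when
  several features are individually weak but jointly informative; on the
  strong fixtures this does not occur.
* `compare_channel_sets` keys reports by the set name, so two identical
  explicit sets collapse to one entry.
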