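# Methods

This note documents the models, formulas, numerical choices and known
limitations behind `nsavoice`. Everything empirical stated here is
computed by the test suite or by `scripts/acceptance.py`.

## The signal model behind the generator

A sustained-vowel vibration token is modelled as a train of
harmonic-stack pulses. Peak *k+1* follows peak *k* after period
`T_k = (1/f0)(1 + c_j·ε_k)` and carries peak amplitude
`A_k = 1 + c_s·δ_k`, with `ε, δ` i.i.d. standard normal. The scales
`c_j, c_s` are solved in closed form so that the relative-perturbation
statistics evaluated on the stored per-cycle series equal the requested
jitter and shimmer exactly: for factors `1 + c·ε` the statistic is
`c·D / (1 + c·ε̄)` with `D = mean|Δε|`, so `c = target / (D − target·ε̄)`.
Targets of zero give perfectly periodic, constant-amplitude trains.

Each output sample is rendered from its *nearest* peak: the local shape
is the five-harmonic cosine stack `g(φ) = Σ wᵢ cos(2π i φ)` (weights
normalized to sum 1, so `g(0) = 1`), the shape period is the enclosing
inter-peak gap, and the amplitude is that of the nearest peak. Three
properties follow, all load-bearing for testability:

* every peak is a smooth interior local maximum whose height equals the
  stored truth amplitude exactly (an amplitude envelope with a knot *at*
  the peak — the obvious alternative — biases sub-sample peak
  interpolation and inflates measured jitter when shimmer is present);
* inter-peak intervals equal the stored truth periods exactly;
* the only artefacts are small amplitude steps at mid-gap points, far
  from every peak, which contribute a weak broadband floor and nothing
  else.

Broadband Gaussian noise is added at a controlled harmonic-to-noise
power ratio (`noise_snr_db`; `inf` = noiseless) — this is the knob that
drives spectral entropy. Optional leading/trailing "silence" carries
Gaussian dither at −80 dB relative to the voiced peak so that
zero-crossing statistics remain defined there.

Harmonic phases are all-zero by default (a cosine stack); a flag
randomizes them. Phase is irrelevant to every feature in scope, but with
randomized phases the waveform peak no longer coincides with the stored
amplitude, so truth-exactness guarantees hold only for the default.

### Per-type templates

| type    | weights (w₁..w₅)            | jitter % | shimmer % | SNR dB |
|---------|-----------------------------|----------|-----------|--------|
| modal   | 3.0, 1.9, 1.15, 0.7, 0.45   | 0.6      | 2.0       | 30     |
| breathy | 6.5, 2.0, 1.0, 0.6, 0.4     | 0.8      | 6.0       | 25     |
| pressed | 2.0, 3.2, 1.6, 0.95, 0.6    | 0.7      | 5.0       | 12     |

The envelopes follow the qualitative spectral picture of phonation on
the vocal-fold-contact continuum: breathy voice concentrates over 60% of
the first-five-harmonic amplitude in H₁ (the template gives H₁ = 0.619);
pressed voice shows a prominent H₂; modal voice decays monotonically.
Modal voice has the smallest shimmer (steadiest loudness), and the
pressed template carries the lowest harmonic-to-noise ratio so that its
spectral entropy is the largest of the three types. The fundamental is
drawn uniformly from 180–250 Hz per token (adult female range) unless
fixed; the recording protocol being emulated constrained neither pitch
nor loudness, so these defaults are conventions, not measurements.

`sample_profile` adds per-token between-speaker scatter (lognormal with
log-sd 0.35 on the weights and perturbation targets, Gaussian sd 4 dB on
SNR, floored at 8 dB). Without it the per-type feature distributions are
nearly point masses and every classifier is trivially perfect; real
cohorts pool dozens of speakers who mimic the target phonation
imperfectly, and their feature ranges overlap. The SNR floor exists
because tokens noisier than ~8 dB would fail any recording quality
screen, and because below it frame zero-crossing rates approach the
broadband limit and voiced/silence gating becomes ill-posed.

### What the generator does *not* emulate

No physiological glottal-flow model (e.g. LF pulses), no vocal-tract or
neck-tissue transfer function, no room or sensor coloration, no
within-token drift of f0 or loudness, no vocal tremor or diplophonia.
Passing tests therefore show that the *pipeline* is correct and that the
discrimination geometry behaves as designed — not that the absolute
accuracies transfer to human recordings.

## Vocal activity detection

Frames of 25 ms advance by 10 ms; energy is the mean squared sample, ZCR
the sign-change count divided by frame duration (crossings/second). A
frame is voiced when

* `energy > min(10 × floor, 0.05 × peak)`, with `floor` the median of
  the lowest-decile frame energies — the relative cap makes detection
  idempotent on records with no silence at all; and
* `zcr < rate/3` by default. Broadband dither crosses at ≈ rate/2
  regardless of sampling rate, while even strongly noisy voiced frames
  (8 dB SNR) stay below ≈ rate/4, so a rate-relative ceiling is the
  robust choice; a fixed crossings-per-second value tuned for 8 kHz
  telephone speech wrongly rejects noisy voiced signal at 44.1 kHz.

The longest contiguous voiced run of at least 0.3 s is the utterance
(one sustained vowel per token by protocol); a run touching the final
frame extends through the uncovered tail, which is what makes re-running
the detector on its own output return the whole segment. All thresholds
are exposed in configuration.

## Features

One Hamming-windowed magnitude spectrum of the whole amplitude-normalized
utterance, zero-padded to ≤1 Hz resolution, serves both spectral
features (matching utterance-level extraction with a single spectrum;
no frame averaging). Choices the defining formulas leave open:

* harmonic amplitude `A_i` = maximum magnitude within ±f0/4 of `i·f0`;
  harmonics above the 1500 Hz band edge contribute `A_i = 0`;
* spectral density for the entropy = squared magnitude (power), and the
  logarithm is natural (nats) by default with the base switchable — the
  uniform-spectrum entropy then equals `ln n` (or `log_b n`);
* `N` in the jitter/shimmer formulas is the number of detected vocal
  cycles. The per-cycle indexing of the sums makes any other reading
  (e.g. the number of waveform samples) inconsistent with the terms
  `|T_i − T_{i+1}|`; jitter and shimmer are kept as fractions internally
  and multiplied by 100 only for display.

f0 estimation is by normalized autocorrelation over a 70–400 Hz search
band with parabolic lag refinement; a peak below 0.3 raises an
"unvoiced" error, which is also the gate that keeps noise-like segments
out of the cycle detector. Cycle detection picks one maximal positive
peak per ~1/f0 window advanced peak-to-peak, refines position and height
parabolically (sub-sample accuracy is what keeps jitter recovery errors
an order of magnitude below the 44.1 kHz sampling quantum), rejects
peaks below 10% of the median peak height (VAD boundaries are
frame-quantized and can leak a few milliseconds of near-silence into the
segment; its "peaks" are dither, and a single silence-to-voice junction
interval would otherwise contaminate the jitter statistic), and finally
discards cycles with periods outside [0.5, 2]/f0.

Amplitude normalization — waveform to unit peak before the spectrum,
spectrum to unit maximum, and the ratio forms of J_r/S_r — makes every
feature invariant under uniform gain, removing loudness from the problem
by construction.

## Screening statistics

Fleiss' κ is computed from the item-by-category count matrix
(`P_i = [Σ n_ij(n_ij−1)]/[n(n−1)]`, chance agreement from squared
category shares); a fully unanimous single-category panel has an
undefined ratio and is returned as κ = 1. The design must be balanced
(equal raters per item). ICC is the two-way random-effects,
absolute-agreement form from the ANOVA mean squares; single-measure
ICC(2,1) by default with the average-measure ICC(2,k) as an option. Both
statistics are cross-checked in the tests against independent
implementations (statsmodels and pingouin) and hand-evaluated small
matrices.

The pure-sample rule is applied as a strict conjunction: a token is pure
iff at least `min_agree` (default 4 of 5) raters chose the same voice
type *and every agreeing rater's* confidence is ≥ `min_conf` (default
0.8). The gate could also be read as applying to the majority's mean
confidence; the strictest reading was chosen and both thresholds are
configurable. "None of the above" can never label a pure sample. The
rule is monotone: raising either threshold never adds a pure sample.

Intra-rater reliability is reported per rater over the duplicated-token
pairs as Cohen's κ on the categories and ICC(2,1) on the confidence
scores with the two presentations as the two "raters".

## Classification

Features are z-scored inside each training fold (the distance- and
gradient-based classifiers are scale-sensitive; the tree and LDA are
indifferent). Classifier fixings:

* DT: Gini criterion, `max_leaf_nodes = 21` ≙ at most 20 binary splits;
* SVM: linear kernel; scikit-learn's SVC trains one-vs-one and predicts
  by pairwise voting with margin-based tie-breaking; exported scores use
  the one-vs-rest transformation for per-class AUC;
* KNN: k = 10, Euclidean, inverse-*squared*-distance weights (one common
  reading of "weighted KNN"; plain inverse distance is a one-line change);
* NN: one hidden layer of 100 units, cross-entropy loss, adam with early
  stopping (patience 25, initial learning rate 5·10⁻³, ≤600 epochs).
  The reference protocol's scaled-conjugate-gradient optimizer is an
  optimizer choice, not part of the model contract; any batch gradient
  method with validation-based early stopping is equivalent here. A
  non-converged repeat is re-seeded once, then raised as an error.

LD/DT/SVM/KNN are evaluated by stratified 5-fold cross-validation with
held-out predictions pooled over folds. The NN uses six repeated random
stratified 70/15/15 train/validation/test splits: the test share is held
out per repeat, early stopping carves the validation share out of the
remainder, reported accuracy is the mean over repeats, and confusion
counts/TPR/FPR/AUC are pooled over all repeats' test sets. AUC is
one-vs-rest per class by the rank statistic. Chi-square comparisons
build a (group × correct/incorrect) contingency from the held-out
predictions; expected cell counts below 1 set a warning flag, and a
degenerate all-correct (or all-incorrect) column returns χ² = 0, p = 1.

## The designed feature cohort

`make_feature_cohort` draws labelled feature vectors directly from
per-type Gaussian distributions. The geometry is sized in d′ units so
that, deliberately:

* shimmer alone separates modal voice (≈3.5 d′ against breathy),
* spectral entropy alone separates pressed voice (≈2.5 d′ against both
  others, which share the same SE distribution),
* H₁ is the strongest quotient cue (largest for breathy), with H₂–H₄
  overlapping heavily,
* jitter is identically distributed across types — a pure-noise feature.

Consequences verified by the tests: removing S_r costs the modal class
well over 10 accuracy points, removing SE costs the pressed class over
5 points, removing J_r moves overall accuracy by well under 2 points,
and breathy voice is the most accurately classified type — the ordering
reported for real cohorts, reproduced here qualitatively and at desk
scale (450 tokens), not numerically.

## Numerical and interface conventions

Sample indexing is 0-based and half-open; times in seconds; frequencies
in Hz. WAV I/O is mono 16-bit PCM via `scipy.io.wavfile` with a
consistent 1/32768 quantization scale, multi-channel inputs reduced to
the first channel with a warning, and premature-EOF files rejected.
Ground truth travels in JSON sidecars next to each WAV. Tables are CSV,
reports JSON; a pipeline run is a pure function of (inputs, config,
seed) and embeds a hash of its configuration. Problem sizes used by the
tests and the acceptance script — 2 s tokens, 150 tokens per class,
16-point recovery grids — are desk-scale choices that keep the full
verification run in the minutes range while leaving every statistical
margin wide.

## Known limitations

* Absolute classification accuracies on synthetic cohorts say nothing
  about human recordings; only the qualitative structure (which features
  matter for which type) is expected to transfer.
* The generator's jitter model is i.i.d. multiplicative period noise;
  real cycle-length sequences are autocorrelated, so real jitter values
  of equal magnitude may behave differently under the consecutive-
  difference statistic.
* The VAD is a two-threshold gate for one utterance per file; it is not
  a noise-robust or multi-utterance segmenter.
* The f0 estimator assumes a quasi-stationary fundamental inside the
  search band; strongly subharmonic or diplophonic signals will confuse
  the period-synchronous cycle picker.
* Confidence values in simulated panels are Beta-distributed
  independently of rating correctness; real raters' confidence
  correlates with their accuracy.
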