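# nsavoice

Voice-type discrimination from neck-surface vibration signals.

Modal, breathy and pressed phonation lie on a continuum of vocal-fold
contact area and open quotient. A miniature accelerometer taped to the
front of the neck records the tissue vibration that carries the
voice-source correlates of that continuum — privacy-preserving (no speech
content) and wearable for all-day monitoring, which makes automatic
voice-type classification from such signals clinically attractive for
vocal-fatigue and voice-dose tracking.

`nsavoice` implements the full discrimination pipeline for
sustained-vowel vibration tokens:

1. **Synthesis** (`nsavoice.synth`) — a ground-truth-bearing generator of
   quasi-periodic vibration signals with per-type harmonic envelopes,
   controllable jitter/shimmer, broadband noise, and silence padding,
   plus simulated expert rating panels. Every downstream stage is
   testable against exact generation truth.
2. **Vocal activity detection** (`nsavoice.vad`) — short-time energy and
   zero-crossing-rate gating isolates the voiced utterance.
3. **Features** (`nsavoice.features`) — the seven-dimensional vector
   **[H₁, H₂, H₃, H₄, SE, J_r, S_r]**:
   - harmonic quotients `H_i = A_i / (A_1 + … + A_5)`, where `A_i` is the
     i-th harmonic amplitude of the Hamming-windowed utterance spectrum
     (50–1500 Hz band, ≤1 Hz resolution); the five quotients sum to one,
     the first four are the features;
   - spectral entropy `SE = −Σ p_i ln p_i` over the normalized power
     spectral density in 0–3000 Hz;
   - jitter `J_r = mean|T_i − T_{i+1}| / mean(T_i)` and shimmer
     `S_r = mean|A_i − A_{i+1}| / mean(A_i)` over per-cycle periods and
     peak magnitudes from period-synchronous peak picking.
4. **Screening** (`nsavoice.screening`) — Fleiss' κ for inter-rater
   agreement, ICC(2,1) (two-way random, absolute agreement) for
   intra-rater reliability on duplicated tokens, and the *pure-sample*
   rule: a token is ground truth only when ≥4 of 5 raters agree on its
   voice type, each with confidence ≥0.8.
5. **Classification** (`nsavoice.classify`) — linear discriminant, medium
   decision tree (20 splits, Gini), linear SVM (one-vs-one), weighted KNN
   (k=10), and a 100-unit single-hidden-layer neural network; stratified
   5-fold CV (NN: six repeated 70/15/15 splits); leave-one-feature-out
   (LOFO) ablation plus spectral `{H₁..H₄, SE}` and stability `{J_r, S_r}`
   subsets; confusion matrices, per-type TPR/FPR/AUC and chi-square
   classifier comparisons.

## Worked example

```python
from nsavoice import PROFILES, synthesize_waveform, extract_features

rec = synthesize_waveform(PROFILES["breathy"], duration_s=2.0, silence_s=0.5, seed=7)
fv = extract_features(rec)
print(fv)
```

prints (f0 drawn at 223.76 Hz for this seed):

```
H1 = 0.6654   # > 0.6: the breathy envelope concentrates amplitude in H1
H2 = 0.1888
H3 = 0.0825
H4 = 0.0413
SE = 1.5802   # nats; tonal signal, low entropy
Jr = 0.0188   # 1.88% relative period perturbation
Sr = 0.0596   # 5.96% relative amplitude perturbation
label = breathy
```

Classifying a 300-token cohort drawn from the per-type feature geometry
and ablating one feature at a time:

```python
from nsavoice import make_feature_cohort, run_lofo
from nsavoice.classify import default_specs

df = make_feature_cohort(n_per_class=100, seed=7)
report = run_lofo(df, specs=default_specs(seed=7))
print((report.overall_accuracy_table() * 100).round(1))
```

```
                   LD    DT   SVM   KNN    NN  set_mean  set_sd
full             95.0  92.3  94.0  93.3  94.8      93.9     1.1
-H1              91.3  90.3  92.3  91.0  91.1      91.2     0.7
-SE              86.3  81.7  86.3  83.0  89.6      85.4     3.1
-Sr              84.0  77.7  84.0  83.0  81.5      82.0     2.6
spectral         84.7  77.7  85.0  83.7  83.3      82.9     3.0
stability        70.3  68.3  72.7  68.0  78.9      71.6     4.5
...
```

Removing shimmer or spectral entropy costs the most accuracy — shimmer
because it is what separates modal voice (the steadiest loudness), and
entropy because it is what separates pressed voice — while removing the
uninformative jitter column changes almost nothing. The stability-only
set `{J_r, S_r}` cannot discriminate all three types.

The same chain runs from the shell:

```sh
nsavoice simulate --type breathy --n 50 --duration 2.0 --seed 7 --out audio/
nsavoice vad --in audio/breathy_0000.wav
nsavoice extract --in audio/ --out features.csv
nsavoice classify --features features.csv --seed 7 --out report.json
nsavoice run --simulate --n-per-class 150 --seed 7 --out run_out/
```

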