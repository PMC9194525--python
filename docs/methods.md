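# Methods

This note documents the models and procedures `filterscope` implements,
the choices made where the design was genuinely open, and what the shipped
synthetic experiments do and do not demonstrate.

## The interpretable CNN

The classifier is a 1-D CNN for fixed-length single-channel windows whose
defining property is a *long* first convolution: at the full-scale defaults
(30-s windows at 100 Hz) the 30 first-layer kernels are 200 weights = 2 s
long, enough to contain an entire physiological waveform such as a
K-complex or a sleep spindle. A long kernel can be read directly — its
time-domain trace is a waveform template, its FFT a spectral signature —
which is what every explanation downstream exploits.

Layer cascade (full-scale sizes): conv1d (30 kernels × 200, stride 1,
ReLU) → max-pool (15, stride 10) → the pooled positions × filters plane is
treated as a one-channel image (time as height, filter index as width) →
conv2d (400 kernels of 30×25, stride 1×1, ReLU) → max-pool (10×1, stride
1×2) → flatten → dense 500 (ReLU) → dense 500 (ReLU) → dense n_classes
(softmax). With 3000-point inputs this gives 2801 → 279 conv/pool
positions, a 250×6×400 conv2d output and a 241×3×400 pooled map. Every
size is configurable; construction validates the cascade and names the
first layer a too-short window breaks.

The engine behind it (`filterscope.nn`) is a float64 numpy implementation
with exact seeded initialization (Glorot-uniform weights, zero biases —
initialization is not dictated by the architecture, so the assumption is
recorded in the model's JSON sidecar) and bit-exact weight get/set
round-trips, the property all perturbation analyses rest on. The 1-D
convolutions run through length-T FFTs restricted to the valid range,
which is exactly the direct sliding dot product up to float rounding
(verified against brute force to ~1e-15) but much cheaper for 100–200-tap
kernels. Determinism: all results in this package are pure functions of
(inputs, seed) on a fixed BLAS; no threading-dependent reductions are
used.

### Training

SGD on class-weighted categorical cross-entropy. Class weights are
inverse-frequency, `n_total / (n_classes · n_k)`. The schedule keys on
validation accuracy with one shared no-improvement counter: "improvement"
means strictly exceeding the best value so far; the learning rate is
multiplied by 0.9 after every 5 consecutive non-improving epochs; training
stops after 20 such epochs or at the epoch cap (full-scale default 30).
Batches of 100, training order reshuffled each epoch. The final-epoch
weights are kept (no best-weight rollback), matching the common default of
early-stopping implementations. Evaluation uses precision, recall and F1
per class from raw confusion counts, with the zero-denominator convention
P = R = F1 = 0, and a support-weighted F1 as the summary.

## Explainability engines

**Spectra and clustering.** Kernel power spectra are `|rFFT(w)|²` on the
`fs/L`-spaced grid, kept from 0 to min(50, fs/2) Hz inclusive. Clustering
is Euclidean k-means on the raw power rows — no log, no normalization —
with k chosen by mean silhouette over a default scan of 2–10 (clipped to
n_filters − 1, 50 initializations) and a final refit with 100
initializations. Ties go to the smaller k. Raw power is the default
because the cluster question is "which kernels extract similar rhythms at
similar strength"; a shape-only variant (row-normalized spectra) can be
had by normalizing before calling the clustering functions.

**Percent-change importance.** All perturbation engines report
`100·(perturbed − baseline)/baseline` for per-class and weighted F1
against a baseline evaluated once per run; negative = important. A zero
baseline F1 makes the corresponding change undefined (NaN), never silently
zero.

**Cluster ablation** zeroes all kernels of one cluster (biases are never
touched — the perturbations target the filters, and the bias pass-through
is part of the "filter removed" condition), re-predicts the held-out test
set, and restores.

**Band perturbation** works per cluster and canonical band: forward FFT of
each member kernel, zero the complex coefficients whose |frequency| falls
in the band (conjugate-symmetric bins together, so the inverse transform
is real to < 1e-9, enforced), inverse FFT, install, predict, restore. The
five bands δ(0–4), θ(4–8), α(8–12), β(12–25), γ(25–50) Hz are half-open
`[lo, hi)` — shared edges belong to the upper band — with the DC bin
assigned to δ and the Nyquist bin to γ when fs = 100. This makes the five
bands an exact partition of the DFT grid, so zeroing every band equals
ablating the kernel outright; that coherence property is tested.

**Temporal ablation** slides a window (default 25 weights, step 1) across
each kernel, zero-padded by half a window on each side so the window
center visits every true weight position. At each center the covered true
weights are zeroed, the test set re-predicted, and the percent changes
recorded as the importance of the center position. Windows covering only
padding or only already-zero weights record exactly 0 without a model
evaluation — the null-perturbation fixed point. With a step above 1
(a speed knob), unevaluated positions inherit the nearest evaluated
center's value so the map stays total.

All three engines restore the original kernels and then *prove* it by
comparing a fresh test-set prediction against the pre-run prediction;
any difference raises an error rather than returning silently corrupted
results.

**LRP.** The αβ rule (α − β = 1 enforced; defaults α=1, β=0) propagates
relevance from the predicted class's pre-softmax score down to the
first-layer ReLU activations. Dense and conv2d layers split each
contribution `a_j·w_jk` by sign; biases enter the denominators (the "0"
index) but receive no relevance, so exact conservation holds only on
bias-free networks — the conservation tests use those. Denominators carry
a sign-matched ε = 1e-9 stabilizer. Max-pooling routes relevance
winner-take-all to the argmax input; this is the standard treatment and
the one consistent with the forward computation. Per-cluster relevance
NR_C sums, per subject and predicted class, the fraction of total
first-layer relevance landing on the cluster's filter channels, adds these
shares over subjects, and scales by `(F − F_C)/F`. That scaling
down-weights *larger* clusters; since the reciprocal reading `F/(F − F_C)`
is also defensible, both are implemented behind a `scaling=` switch with
the `(F − F_C)/F` form as the default. Subjects contributing zero total
relevance for a class are excluded with a logged warning.

## The synthetic generator

`generate_dataset` emulates the statistical shape of preprocessed
single-channel sleep EEG while keeping each class's discriminative content
exactly known. Per window: colored noise with PSD ∝ 1/f^exponent
(white-noise FFT shaped by f^(−exponent/2), normalized to unit sd, exactly
seedable), plus the class's band components — narrowband Gaussian
processes with random phase, rms amplitude expressed in noise-sd units,
degenerating to a pure random-phase sinusoid below one bin of bandwidth —
plus transients at Poisson counts with uniform start times truncated at
the window edge. Two transient shapes are provided: a negative-then-
positive half-sine pair of 0.5–1 s (K-complex-like) and a Hann-windowed
carrier burst (spindle-like). Class imbalance is expressed through class
priors. Per-recording standardisation (`zscore_per_subject`) and
subject-wise random splits mirror the preprocessing and evaluation
hygiene of real sleep-staging work.

What the generator does *not* emulate: non-stationarity within a
recording, artifacts (movement, electrode pops), stage-transition
structure between adjacent windows, inter-subject spectral variability,
or multichannel covariance. Passing the recovery tests therefore shows
the *engines* are sound — that they find planted truth when it exists —
not that the classifier or its explanations reach any particular quality
on real polysomnography.

## The reduced validation experiment

`example_reduced_config` is the package's desk-scale study: 3 classes ×
8 subjects × 60 windows of 10 s at 100 Hz, and a 12-kernel model with
1-s first-layer kernels (filter2 20×12, pools unchanged in spirit, dense
50+50). Its design went through explicit regime analysis:

- **Signal strength.** Each class plants one weak random-phase narrowband
  oscillation in a distinct canonical band — δ: 2 Hz, β: 13 Hz, γ: 30 Hz —
  at rms amplitude 0.25 over unit-sd 1/f noise. Weak signals are
  essential, not incidental: with strong tones (amplitude ≳ 0.5) the task
  saturates within a few epochs, cross-entropy gradients vanish, and the
  first-layer kernels never leave their random initialization — the
  trained "spectra" are then initialization noise and no clustering of
  them is meaningful. At amplitude 0.25 validation accuracy climbs over
  much of the run, the regime where the first layer is forced to become a
  spectral detector.
- **First-layer initialization scale.** The first layer starts at 0.1 ×
  Glorot. At this data scale a training run applies ~600 gradient updates
  (versus roughly a thousand times more at full scale), which is not
  enough to overwrite a full-scale random initialization; a small start
  lets the trained kernels show what was learned. This is a choice about
  the *visualized* layer only; all other layers keep standard Glorot.
- **Schedule scaling.** Epoch-denominated settings are scaled up (200
  epochs maximum, learning-rate patience 50, early-stop patience 200)
  because an epoch here is 3 updates; the full-scale defaults remain the
  printed schedule.
- **Clustering space.** The reduced configuration clusters
  shape-normalized spectra (each row divided by its total,
  `spectra_preprocess="shape"`). With only a dozen kernels whose overall
  magnitudes vary more than their spectral identities, raw-power k-means
  groups by magnitude and the silhouette scan tends to merge spectrally
  distinct single kernels; normalizing to spectral shape restores the
  band structure as the clustering signal. The full-scale default remains
  raw power.

The recovery study (`filterscope.validation`) trains this configuration on
five seeds and scores, per seed: (i) whether the silhouette-selected k
equals the number of planted spectral groups (three); (ii) whether, for
each class, the cluster carrying its planted band (largest center power
fraction in the band) shows the class's most negative ablation change;
(iii) whether, inside that cluster, zeroing the planted band hurts the
class more than zeroing any of the other four bands. In development runs
the ablation and band recoveries held in 5/5 seeds across every regime
tested once the non-saturating regime was established; the k-selection
criterion is the most delicate of the three, because silhouette
differences between merging or splitting one strong kernel's singleton
cluster are small — the per-seed silhouette curves are the diagnostic to
inspect when it misses.

Problem sizes throughout (toy networks of ≤ 50 units for the propagation
oracles, 1,000 random label vectors for the metric oracle, the reduced
experiment for recovery and restoration) were chosen so the full suite
runs on one CPU in minutes while still exercising every code path at
realistic shapes.

## Known limitations

- The numpy engine implements exactly the layer set this architecture
  needs; it is not a general deep-learning framework (no striding in
  convolutions beyond 1, no GPU, no autograd beyond the implemented
  layers).
- Silhouette-based k selection on a dozen spectra is inherently
  small-sample; for real 30-filter banks the scan range and any spectra
  normalization deserve a sensitivity check.
- LRP conservation is exact only without biases; with biases a share of
  relevance is absorbed, as in standard αβ practice.
- The monotonicity of ablation (a superset of filters hurting at least as
  much as a subset) is *not* guaranteed by theory and is deliberately not
  asserted anywhere; occasional inversions from prediction noise are
  expected.
- Temporal ablation evaluates the full test set at every window position;
  the `step` knob trades resolution for time on large test sets.
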