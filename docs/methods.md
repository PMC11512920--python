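# Methods

This note documents the models, numerical choices and limitations behind
`cfsimage`.  It complements the README, which describes the analysis path
itself.

## The synchronisation measure

At one electrode, for frequency bands *A* and *B*, the package measures the
resultant length of the time-averaged unit phasors of the instantaneous
phase differences,

    S_CF = | (1/n) Σ_t exp(i (φ_A(t) − φ_B(t))) |,

the intra-electrode, cross-band variant of intersite phase clustering.
Phases come from the analytic signal of the band-filtered channel.  The
differences are taken 1:1 — no n:m frequency-ratio scaling — matching the
measure's printed definition; an `(n, m)` generalisation is exposed on
`cfs_value`/`cfs_matrix` for conventional n:m locking studies but defaults
to (1, 1).

Two closed forms anchor the estimator's calibration and are enforced by the
test suite:

* von Mises phase jitter at concentration κ gives an expected resultant of
  `I₁(κ)/I₀(κ)`;
* independent uniform phases give a mean resultant of `√(π/4n)` (the
  Rayleigh level; 0.0177 for the 5 s, 500 Hz segments used here).

**A structural property of the 1:1 measure.**  Because a linear-phase filter
bank separates components by frequency, the analytic-phase difference of two
*distinct* components ramps at their carrier separation, and its segment
resultant is driven to zero regardless of how the phase residuals are
locked.  High 1:1 cross-band CFS therefore requires one and the same
oscillation to pass both band filters — possible only near a shared
passband edge of adjacent bands.  This is a property of the measure itself,
not of the implementation, and it shapes both the synthetic generator
(below) and the interpretation of cross-band CFS topographies on real data.

## Band filters and phase

Hamming-window FIR band-pass filters; length from
`L = ceil(3.3/Δf · fs)` rounded up to odd, transition bandwidth
`Δf = min(max(0.25·f_low, 2 Hz), f_low)`.  At 500 Hz this reproduces the
conventional lengths for all five bands (3301/825/825/551/221); explicit
lengths may override the rule.  The constant group delay `(L−1)/2` is
removed by shifting, so phase relations are preserved exactly; the first and
last `(L−1)/2` samples involve zero-padded edges and are flagged in the
`PhaseTensor` (`edge_samples`) but kept, so a 150 s recording yields exactly
30 segments.  The Hilbert transform is applied to the full-length filtered
signal *before* segmentation (filter → phase → segment), avoiding windowing
artefacts in the phase estimate.  Phase is reported wrapped by default;
the measure is wrap-invariant, and unwrapped phase is available.

## Montage, projection, imaging

The default montage is an idealised spherical 10-20/10-10 layout of the 32
electrodes of a standard 32-channel cap, constructed geometrically from the
arc-fraction rules of the 10-20 system (midline and ring electrodes at 10%/
20% arcs, intermediate rows by spherical interpolation, inferior row 10%
below).  Construction on the sphere makes the layout exactly mirror-
symmetric and exactly sphere-bound — properties digitised montages only
approximate — which the projection-geometry guarantees (radial-order
preservation, homologous mirror symmetry) rely on.  Digitised montages load
through the `.sfp` reader.

Projection is azimuthal equidistant about the Cz reference: `ρ = R·c` with
`c` the angular distance from Cz, `x = ρ sin θ`, `y = −ρ cos θ` with the
azimuth measured from the anterior direction.  Interpolation is
Clough–Tocher (C¹ piecewise cubic on the Delaunay triangulation) on a 32×32
mesh.  Choices the method's description leaves open, fixed here:

* the mesh bounding box is square, covers the projected cloud plus a 5%
  margin, and is shared by all layers, frames and the feature mask, so
  pixels align across the pipeline;
* out-of-hull pixels take fill value 0 (zero synchronisation renders
  black);
* stored frames keep raw CFS values in [0, 1] with no per-frame
  normalisation (display normalisation is cosmetic only); cubic overshoot
  is clipped back to [0, 1];
* the feature mask assigns every in-hull pixel to its nearest projected
  electrode (a planar Voronoi partition restricted to the hull) — a
  deterministic realisation of "the pixels most affected by each
  electrode"; each electrode additionally owns its nearest pixel even when
  that pixel centre falls marginally outside the hull (relevant for
  hull-vertex electrodes).

## Synthetic EEG generator

The generator emulates the acquisition geometry of a paediatric
auditory-EEG study: 31 Cz-referenced channels, 500 Hz, 150 s per recording,
1/f background noise (spectrally shaped white noise, exponent default 1.0),
per-band background oscillators at the bands' geometric mid-frequencies with
slow phase drift (decoherence time ≈ 1 s), and per-channel z-scoring.
Cz referencing is emulated by generating the 31 non-reference channels
directly.  Per-subject seeds are `seed + subject index`; generation is
bit-reproducible.

**Coupling injection.**  Following the structural property above, a
prescribed coupling between adjacent bands at one electrode is injected as a
single shared carrier at the filter-edge frequency (12 Hz for Alpha–Beta,
30 Hz for Beta–Gamma).  Both filters pass the carrier at ≈ half amplitude;
each filtered signal is then carrier + that band's background oscillator +
in-band 1/f noise, and the measured synchronisation is set by the
carrier-to-interference ratio.  The carrier amplitude is solved from the
requested level using two closed forms, treated as independent factors per
band:

* a constant-amplitude interferer at amplitude ratio *u* multiplies the
  expected resultant by `f(u) = (1/2π)∫ (1+u cos α)/√(1+2u cos α+u²) dα`;
* in-band Gaussian noise at SNR ρ multiplies it by the Rician phase
  resultant `√(πρ)/2 · e^(−ρ/2) [I₀(ρ/2)+I₁(ρ/2)]`.

Measured subject-mean CFS tracks the target within ≈ 0.02 for targets
0.8–0.95 and ≈ 0.05 mid-range (the independence approximation is the main
error source).  Targets are capped at 0.995 (a target of exactly 1 needs an
infinite carrier).  For *disjoint* pairs no carrier passes both filters; the
generator falls back to von-Mises-jittered shared phase residuals
(calibrated through the Bessel-ratio inversion `coupling_to_concentration`)
and warns that a 1:1 estimator cannot detect the coupling after filtering.
Couplings can be gated to a segment range, with 0.2 s cosine cross-fades.

**Default class templates.**  Both classes share a Pz Alpha–Beta coupling
(0.6).  The class difference sits at three electrodes: FC5 Alpha–Beta is
0.9 in controls and 0.3 in dyslexics (a graded decrease of left
fronto-temporal synchronisation), and dyslexics add TP9 Alpha–Beta 0.9 and
PO9 Beta–Gamma 0.8.  Electrode choices follow qualitative group differences
reported in auditory-EEG dyslexia work (left fronto-central electrodes
discriminating controls; a sustained left temporo-parietal increase in
dyslexic readers); the magnitudes and band pairs are fixture choices —
couplings are placed on adjacent band pairs because only those are
detectable by the 1:1 measure.  The cohort default is 33 controls and 15
dyslexics, mirroring the class imbalance typical of such studies.

**What the generator does not emulate** — and hence what passing benchmarks
do not show about real data: volume conduction and spatially correlated
noise, stimulus-locked evoked responses, artefacts, inter-subject montage
variability, and any physiological cross-frequency mechanism beyond the
shared-edge-carrier construction.  The benchmark demonstrates that the
pipeline recovers class-dependent synchronisation topographies it is able
to express, not that such topographies exist in any clinical population.

## Classifier

Per frame: two convolution blocks (conv → batch-norm → ReLU), defaults 8 and
16 filters, 3×3 kernels, stride 1 then 2 (the second stride bounds the
flattened size), then flattening.  Per sequence: a two-layer stacked LSTM,
hidden size 20; dropout 0.5 on the hidden-state sequence; the flattened
hidden sequence feeds two fully-connected layers (width 20, then 2 logits).
The engine is a compact NumPy implementation (im2col-free convolution,
standard batch-norm and BPTT gradients, Adam) — adequate because the models
are small and the cohorts number tens of subjects; an end-to-end
finite-difference gradient check is part of the suite.

The optimisation recipe (not prescribed by the architecture): full-batch
Adam at 1e-3, cross-entropy with inverse-class-frequency weights, early
stopping when the 5-epoch-smoothed training loss stops improving.
Evaluation is subject-stratified 5-fold cross-validation — the unit is the
subject's sequence, so test-subject frames never reach training — with
per-fold re-initialisation from a fold seed.  Sensitivity `TP/(TP+FN)`,
specificity `TN/(TN+FP)`, balanced accuracy (their mean, robust to class
imbalance) and rank-statistic AUC are reported as mean ± sd over folds.
Separate stimuli or band-pair triplets are analysed as separate runs.

The benchmark experiments (`cfsimage.benchmark`) use a deliberately small
instance — 4 and 8 filters with strides 2 and 4 (128 features/frame), 160
epoch budget — so a full cross-validated run takes a couple of minutes on
one CPU; the null-benchmark permutations use a smaller instance still (2/4
filters, 12 epochs), since training to convergence on permuted labels
cannot create out-of-fold skill and the null check only asks that chance
level is respected.  With those sizes the separable benchmark reaches
balanced accuracy and AUC of 1.0, and each of 20 label permutations of an
identical-template cohort scores 0.50 (the under-trained network is an
effectively constant predictor, the honest chance-level behaviour).

## Explanation

Frame-wise LIME over the 31 electrode super-pixels: for one frame, random
subsets of super-pixels are switched off (independent fair bits; the
all-ones design is always sample 0; switched-off pixels are set to 0,
consistent with the imaging fill; mean-fill is available), the other 29
frames stay untouched.  The surrogate is a lasso fitted to the classifier's
response, weighted by `exp(−D²/width²)` with D the Euclidean pixel distance
between original and perturbed frame.

Numerical choices that depart from common LIME defaults, and why:

* **Target = class log-odds**, not probability.  A well-separated
  classifier saturates its softmax; single-frame perturbations then leave
  probabilities numerically constant and every coefficient collapses to
  zero.  The log-odds (logit margin) is a monotone transform of the same
  probability and stays responsive.
* **Scale-adaptive kernel width.**  The conventional `0.25·√d′` width is
  meant for distances on the binary design; applied to pixel distances it
  gives the informative perturbations (those switching off bright
  super-pixels) weights of order e^-5, and the surrogate degenerates.  The
  default width is `√(2·median D²)` over the drawn perturbation set, which
  gives the median perturbation weight e^-0.5 at any image contrast;
  a fixed width (including `0.25·√d′`) can be passed explicitly.
* **Fixed lasso penalty** (1e-3) rather than per-frame tuning, for
  determinism; the zero-penalty limit against closed-form weighted least
  squares is a tested oracle equivalence.
* Perturbing one frame leaves the other frames' convolutional features
  unchanged, so per-frame CNN features and LSTM prefix states are cached
  and only the suffix is re-run per sample — verified to be numerically
  identical to full evaluation.

Explanations default to the model's predicted class for the subject;
aggregation over subjects (e.g. only correctly classified ones, per class
or pooled — both readings of "the given class" are supported) averages
coefficient maps and ranks the top-5 super-pixels per frame, rendered green
(positive) / red (negative).

## Benchmark problem sizes

Chosen once, as the package's experimental design: separable and null
cohorts of 33+15 subjects at full recording length (150 s, 30 frames);
5-fold cross-validation; 20 label permutations for the null; 1 000 LIME
perturbations per frame for the recovery experiment (the reporting default
elsewhere is 10 000).  The recovery statistic is the share of (correctly
classified subject, frame) pairs whose top-5 super-pixels include an
injected-difference electrode (FC5, TP9 or PO9).

## Known limitations

* The 1:1 CFS measure cannot register cross-band coupling between
  spectrally disjoint bands (see the structural property above); Theta–Gamma
  layers of real or synthetic data are expected to sit at the noise floor.
  n:m locking would need the exposed `(n, m)` ratio and a matched generator
  mechanism, both out of the default path.
* Von Mises jitter calibration applies exactly at the phase level; the
  pipeline-level calibration of the edge-carrier mechanism is approximate
  mid-range (± ≈ 0.05).
* The EDF writer is minimal (16-bit, 1 s records, integer sampling rates);
  the BrainVision path is read-only via `mne`.
* Batch normalisation statistics come from full-batch training; very small
  training sets make them noisy.
* Explanations inherit LIME's locality and collinearity caveats: relevance
  splits across neighbouring super-pixels when an interpolated blob spans
  several of them.
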