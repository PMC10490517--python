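# Methods

## Problem setting

A driver in a motion simulator completes three manual sessions on a 14 km
highway with six road-works chicanes (200 m each, 2 km apart, the first at
2 km, driven at ~120 km/h, ~7 min per session) and one autonomous session
(the same 7 min route followed by 13 min without obstacles). Manual
driving demands continuous control and is taken as *high mental
engagement* (class 0); supervised autonomous driving is *low engagement*
(class 1). Six EEG channels, two skin-potential (SPR) electrodes and two
ECG leads are acquired at 200 Sa/s on a common time base, alongside a
vehicle-dynamics trace at the same rate.

## Signal model of the synthetic cohort

The original recordings are distributed on request only, so the package
carries a generator whose defaults emulate the study design (19 subjects,
3 × 420 s manual + 1200 s autonomous, 200 Sa/s). Engagement enters
through three class-conditional effects, each a config parameter rather
than a claim about effect magnitude in real physiology:

* **EEG** — per channel, a 1/f background plus band-limited Gaussian
  noise in delta (1–4 Hz), theta (4–8), alpha (8–13) and beta (13–30)
  bands. Under high engagement the frontal theta RMS is multiplied by
  (1 + δ) and occipital alpha divided by (1 + δ); δ defaults to 0.5, with
  presets δ = 0 (`null_effects`) and δ = 2 (`strongly_separable`).
  Band-limiting is done by FFT masking, which is exact and fast.
* **ECG** — a PQRST train of five Gaussian bumps (P −0.20 s/0.12 mV,
  Q −0.03/−0.15, R 0/1.0, S 0.03/−0.20, T 0.22/0.30; widths 10–50 ms)
  at the class heart rate with 4 % RR jitter; lead 2 is a scaled (0.7×)
  projection of the same source. Defaults 80 bpm manual / 68 bpm
  autonomous; the separable preset uses 85/65.
* **SPR** — a shared slow tonic baseline (< 0.05 Hz) plus phasic events
  with ~0.8 s rise and 3 s decay at a class-dependent Poisson rate
  (default 6/min manual vs 2/min autonomous; separable preset 8 vs 1),
  with independent per-hand sensor noise.

Artifacts are injected separately, with exact locations returned as
ground truth: correlated blink bumps on Fp1/Fp2, sub-hertz sinusoidal
drift on C3/C4, decaying step ("electrode pop") artifacts on O1/O2,
0.6 s motion spikes on alternating SPR hands, 0.2–0.3 Hz respiration
wander on both ECG leads, and dropped-packet zero runs written per sensor
group (all six EEG channels zero together, each SPR hand and the ECG pair
separately) — matching an acquisition chain in which each wireless sensor
stalls as a unit.

What the generator does **not** model: volume conduction and channel
covariance structure, non-stationary engagement within a session, eye
movements other than blinks, ECG morphology variation, or any coupling
between driving events and physiology beyond the class labels. Passing
tests on this cohort therefore demonstrate that the pipeline and
classifiers recover class structure of the kinds injected — spectral,
cardiac-rate, and electrodermal-rate differences — not that they would
reach any particular accuracy on real recordings.

The manual-session speed profile is the mean speed plus a slow (< 0.02 Hz)
5 % modulation, kept strictly positive so the position↔time map is
invertible; the autonomous session drives at exactly the mean speed.

## Cleaning pipeline

Order: zero-gap repair → alignment → notch → per-modality cleaning →
synchronized excision → windowing. Every removal stage applies one index
mask to all channels so the modalities never de-synchronize.

* **Zero-gap repair.** A sample is a dropped sample iff its stored value
  is exactly 0.0 (the acquisition GUI writes literal zeros); interior runs
  are linearly interpolated between nonzero neighbors, edge runs take the
  nearest value. A `min_run_length` guard (default 1 = repair everything)
  can protect isolated true zero crossings. The repair is idempotent.
* **Alignment.** The simulator trace defines the session length; the
  recording is truncated to it. A recording more than 1 s shorter than
  its trace indicates a synchronization fault and errors out.
* **Notch**: 4th-order Butterworth band-stop, 46–54 Hz, forward–backward
  (zero phase). The real-time causal variant used during acquisition is
  out of scope.
* **EEG band-limit**: windowed-sinc FIR (Hamming), high-pass 4 Hz with
  2 Hz transition (331 taps at 200 Sa/s) then low-pass 45 Hz with 5 Hz
  transition (133 taps); odd tap counts with 'same'-mode convolution give
  exact group-delay compensation, so EEG events stay aligned with SPR/ECG.
* **Gross-amplitude rejection** replaces manual visual inspection: any
  1 s block in which an EEG channel exceeds 500 µV (configurable) is
  flagged; flagged blocks are excluded from ASR calibration and removed
  (across all channels) before windowing.
* **ASR**: calibration selects the cleanest 1 s blocks by worst-channel
  RMS z-score up to 60 s; the calibration covariance gives a mixing
  matrix M = C^{1/2} and whitening W = C^{-1/2}; per-component thresholds
  are mean + k·std (k = 20) of sliding-window RMS of the whitened
  calibration data. Each 0.5 s half-overlapping window is
  eigendecomposed in the whitened space; thresholds are rotated into the
  window basis, and components exceeding them are removed by orthogonal
  projection (X_clean = M·U·diag(keep)·Uᵀ·W·X) rather than EEGLAB's
  least-squares reconstruction — simpler, and identical when no component
  is flagged, which bounds distortion of clean data. Windows are blended
  by Hann overlap-add.
* **SPR fusion**: local energy = moving average (1 s) of the squared
  first difference; at each sample the lower-energy hand is selected, and
  the binary selection is smoothed by a 0.1 s raised-cosine kernel into a
  cross-fade weight. Ties select the right hand (SPR1).
* **ECG lead selection**: SNR = power in the 5–25 Hz QRS band over
  (power outside 0.5–40 Hz plus a robust broadband-noise floor, the
  squared scaled MAD of the > 40 Hz component). Ties select lead 1. The
  chosen lead is high-passed at 0.5 Hz (Butterworth order 2,
  forward–backward), which removes respiration wander while changing
  R-peak amplitudes by < 5 %.
* **Obstacle excision** removes samples whose longitudinal position lies
  in [p − 500 m, p + 200 m + 500 m) for any obstacle start p — positions
  are known track layout, not detected. Intervals are half-open on
  0-based sample indices.
* **Windowing**: consecutive non-overlapping windows of
  round(window_s · fs) samples (600 at the 3 s default), cut per session
  on the concatenated post-excision signal, trailing remainder dropped;
  the segment count per session is ⌊cleaned length / window⌋.

## Classifiers

The network engine is NumPy throughout (channels-last layout; every
convolution is one BLAS GEMM). Architectures are described in the README;
further choices:

* Batch-norm affine parameters count as trainable; running statistics do
  not. The inference statistics are **not** a momentum running average:
  after training (and weight restoration) they are set exactly from one
  pass over the training set with dropout disabled. At the segment counts
  this package typically trains on, a momentum estimate would still be
  far from the activation statistics when training stops, and
  inference-mode outputs would not match training behavior.
* Early stopping needs a monitored quantity the source experiment does
  not name; a seeded stratified 10 % split of the training segments is
  carved off and its cross-entropy (computed with batch statistics)
  monitored; the best epoch's weights are restored.
* Inputs are standardized per channel with training-set statistics —
  microvolt EEG and millivolt SPR/ECG differ by orders of magnitude and
  the data-level network concatenates them into one array.
* The L2 penalty (1.3 data-level / 0.7 feature-level) applies to
  dense-layer weight matrices only, as loss += λ‖W‖²; Adam's learning
  rate defaults to 1e-3 and is configurable.
* Argmax ties at prediction break toward class 0.
* `dense_hidden=0` builds the feature-level network without its 500-unit
  layer (the published ablation), wiring the concatenated branch features
  directly to the softmax head.
* Max-pool ties (equal neighbors) take the earlier sample; odd time
  lengths floor.

## Evaluation protocol

LOSO: for each subject, train on the balanced union of all other
subjects' segments and test on all of that subject's segments. Balancing
is seeded random undersampling of the majority class — undersampling
rather than oversampling so no duplicated segment can land on both sides
of the early-stopping split. Test sets are never balanced. The *positive*
class for sensitivity/specificity is class 0 (high engagement),
configurable; BA and GM are computed on the fractional scale and reported
in percent. A fold whose test set lacks a class leaves the affected
metrics as missing (NaN) and is excluded from that metric's cohort mean
with a logged note — not coerced to zero. Cohort aggregation is
mean ± sample standard deviation (ddof = 1) over folds. Per-fold
confusion matrices are stored normalized to percent of total. Each fold
derives its seed as (1009·seed + fold) mod 2³¹, so folds are independent
but the whole cross-validation is reproducible.

The window-length sweep re-segments cleaned recordings at each requested
length and rebuilds the networks (the flatten width follows the pool
floor rule); lengths below the architecture's minimal valid input
(76 samples for four blocks) are reported as per-length errors rather
than aborting the sweep.

## Problem sizes in the test suite

The LOSO checks run on a reduced cohort chosen as the package's test
scale: 5 subjects, three 90 s manual sessions and a 189 s autonomous
session each (153 segments/subject: 90 high + 63 low), artifact-free
generation, and a shortened training budget (learning rate 3e-3; 3 epochs
for the data-level network, 5 for the feature-level one, whose ~68×
larger parameter count needs more optimizer steps) — enough for both
architectures to exceed 70 % mean LOSO accuracy
on the strongly separable preset while a zero-effect cohort stays at
chance. Model unit tests use 100-sample windows, which exercise the same
conv/pool code path at a fraction of the cost.

## Known limitations

* ASR uses the projection variant above; outputs will not match EEGLAB's
  `clean_rawdata` sample-for-sample, though both remove the same
  subspaces on well-separated artifacts.
* The generator's channels are conditionally independent given the class;
  spatial-filter learning (the spatial convolution's purpose on real EEG)
  is under-exercised.
* Training on CPU in float32 is reproducible bit-for-bit for a fixed
  seed, BLAS and NumPy version, but not across BLAS builds.
* The SNR-based ECG lead selector assumes at least 10 s of signal.
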