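# mindfuse

Multimodal biosignal fusion for classifying a driver's mental engagement.

During assisted and autonomous driving, a driver's attention disengages
from the driving task; detecting that state from wearable sensors is a
prerequisite for safe hand-over. `mindfuse` implements a complete pipeline
for one instance of this problem: six-channel EEG (Fp1, Fp2, C3, C4, O1,
O2), two skin-potential-response (SPR) electrodes (one per hand) and two
ECG chest leads, all sampled synchronously at 200 Sa/s in a driving
simulator, with manual-driving sessions labeled *high engagement* (class 0)
and an autonomous session labeled *low engagement* (class 1).

The package provides:

* **I/O** for the synchronized-recording CSV dialect
  (`time,Fp1,Fp2,C3,C4,O1,O2,SPR1,SPR2,ECG1,ECG2`), linear repair of
  dropped-packet zero runs, and alignment to the simulator's
  vehicle-dynamics trace;
* **cleaning**: 46–54 Hz Butterworth notch, 4–45 Hz linear-phase FIR
  band-limit plus artifact subspace reconstruction (ASR) for the EEG,
  local-energy fusion of the two SPR channels into one motion-robust
  signal, SNR-based ECG lead selection with a 0.5 Hz IIR high-pass, and
  excision of obstacle-traversal spans (200 m works zone + 500 m margins)
  located through the vehicle's longitudinal position;
* **segmentation** into non-overlapping 3 s windows (600 samples × 8
  cleaned channels) labeled by session;
* **two deep ConvNet classifiers** built on a NumPy network engine written
  for this package — a *data-level fusion* network that consumes one
  600 × C array (C ∈ {6, 7, 8} channels), and a *feature-level fusion*
  network with one four-block ConvNet branch per modality, concatenated
  and fed through a 500-unit dense layer and a softmax head;
* **leave-one-subject-out (LOSO) evaluation** with balanced training
  folds, unbalanced test folds, and five metrics per fold — accuracy,
  sensitivity, specificity, balanced accuracy BA = (Se + Sp)/2 and
  geometric mean GM = √(Se·Sp) — aggregated as mean ± std over subjects;
* a **synthetic cohort generator** that emulates the experiment
  (19 subjects, three ~7 min manual sessions, one 20 min autonomous
  session, engagement-dependent band power, heart rate and electrodermal
  event rate, plus blink/drift/pop/spike/zero-run artifacts with exact
  ground truth), since the original recordings are not public.

## Architecture

Both classifiers follow the four-block deep ConvNet recipe for raw
biosignal decoding. Block 1 applies a temporal convolution (25 filters,
kernel 5 along time) and — for multi-channel inputs — a spatial
convolution spanning all channel rows, then batch-norm, ELU, max-pool
(size 2, stride 2, floor) and dropout; blocks 2–4 repeat with 50/100/200
filters. A 600-sample window contracts along time as

```
600 → 596 → 298 → 294 → 147 → 143 → 71 → 67 → 33
```

leaving 200 × 33 = 6 600 features per branch. Trainable-parameter counts
(weights, biases and batch-norm scale/shift):

| sensors          | data-level | feature-level |
|------------------|-----------:|--------------:|
| EEG              |    149 477 |     3 437 777 |
| EEG+SPR, EEG+ECG |    150 102 |     6 870 277 |
| EEG+SPR+ECG      |    150 727 |    10 302 777 |

Training uses Adam on categorical cross-entropy, batch size 128, L2
penalty on dense-layer weights (1.3 data-level / 0.7 feature-level), and
early stopping (patience 50 of max 200 epochs data-level, 20 of 50
feature-level) on a stratified validation split.

## Worked example

```
$ mindfuse simulate --out cohort --seed 5 --config examples/small.yaml
cohort of 2 subject(s) written to cohort
$ mindfuse preprocess --cohort cohort --out segments.npz --config examples/small.yaml
160 segments written to segments.npz
$ mindfuse evaluate --archive segments.npz --arch data --sensors all --seed 3 \
      --config examples/small.yaml --out results
accuracy: 38.8 +/- 19.4 %
sensitivity: 26.7 +/- 37.7 %
specificity: 75.0 +/- 35.4 %
balanced_accuracy: 50.8 +/- 1.2 %
geometric_mean: 25.8 +/- 36.5 %
results written to results
```

The printed numbers are the cohort mean ± standard deviation over LOSO
folds; per-fold confusion counts and metrics land in
`results/loso_results.json`. A two-subject toy cohort with the default
(moderate) effect sizes and a one-epoch training budget sits at a
balanced accuracy of 50 % — chance, as it should: each fold trains on a
single subject for one epoch. The LOSO tests in
`tests/test_acceptance.py` show the separation achieved on a 5-subject
cohort with large configured effects, where both architectures exceed
70 % mean accuracy while a zero-effect cohort stays at chance.

Counting parameters without training:

```
$ mindfuse evaluate --arch feature --sensors all --count-params-only
feature_fusion eeg+spr+ecg: 10302777 trainable parameters
```

## Layout

```
src/mindfuse/
  io_formats.py     recording/trace CSV I/O, zero-gap repair, alignment
  synthetic.py      cohort generator with ground-truth bookkeeping
  preprocessing.py  notch/FIR/ASR/SPR-fusion/ECG chain, excision, windows
  nn.py             NumPy conv-net engine (layers, Adam, cross-entropy)
  models.py         the two fusion architectures, training, inference
  evaluation.py     LOSO protocol, balancing, metrics, window sweep
  cli.py            simulate / preprocess / evaluate / sweep commands
docs/methods.md     model and design notes
```
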