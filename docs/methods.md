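# Methods

This note records the models implemented, the defaults chosen where the
design was open, and what the synthetic study does and does not show.

## The transform

`pmat.core` implements the moving average `MA(X, j, w)` (1-based start
`j`, window `w ∈ [2, n]`), the three padded variants and the stacked
transform.  Conventions that required a decision:

* **Indexing.** All public formulas and errors speak 1-based, matching
  the defining equations; storage is 0-based with row `r` holding window
  size `w = r + 1`.  `PMATMatrix.display()` flips to the
  window-descending orientation used in print.
* **Centered padding.** The total padding of `w − 1` copies splits as
  `⌊(w−1)/2⌋ + p` on the left and `⌊(w−1)/2⌋` on the right, `p = 1` for
  even `w`.  The parity identity (left + right = w − 1) is tested for
  all `w`.
* **Accumulation.** Series are computed with a cumulative sum; the test
  suite pins agreement with an independent direct-summation oracle to
  1e-12 relative error, and the rational worked examples to 1e-9
  absolute.
* **`w_max` default.** Nothing fixes the maximum window for heartbeat
  images, and the transform's stated `O(N²)` cost corresponds to
  `w_max ≈ n`.  Default: `w_max = n` (the segment length), so the raw
  matrix is square and keeps every scale; it is a config knob.
* **Resizing.** Bilinear interpolation (scikit-image, `order=1`,
  anti-aliasing off, edge mode), default target 120×120.  Bilinear
  output is a convex combination of inputs, so the `[min, max]` range
  confinement of the matrix survives resizing.

## Preprocessing

* **Baseline removal.** Baseline = `median600ms(median200ms(x))`,
  subtracted from the raw signal.  Kernel sizes are `round(width · fs)`
  forced odd (symmetric medians need odd windows); edges use reflect
  padding to avoid artificial steps.  Measured on a pure 0.3 Hz
  unit-amplitude sinusoid at 360 Hz, the interior residual is ≈ 0.04;
  reflect padding distorts roughly one second at each record end (the
  test asserts away from edges).  QRS-like impulses pass through within
  5 % of their amplitude.
* **Scaling.** Per-heartbeat min–max scaling to [0, 1].  The scaling
  unit is the segmented beat — the same unit the classifier consumes.
  A constant segment (a flat-lined beat) scales to all zeros with a
  warning rather than raising.
* **Segmentation.** Duration-based: samples in
  `[peak − 0.25 s · fs, peak + 0.45 s · fs)`, covering P through T at
  normal rates.  Different sampling rates (360 / 257 / 250 Hz across the
  three databases) therefore give different sample counts for the same
  time span; no resampling is done — the image resize absorbs the
  difference.  Beats whose window overflows the record, or which lack a
  neighbouring beat, are excluded and counted in a ledger.
* **RR features.** pre-RR, post-RR, local-RR and ratio-RR = pre/post,
  all in seconds (ratio dimensionless).  local-RR averages up to ten
  preceding intervals; beats with fewer use all available, and beats
  with none are excluded — this keeps early beats usable without
  leaving the feature undefined.

## Databases and filters

Beat symbols map to AAMI classes via the standard annotation table
(N,L,R,e,j → N; A,a,J,S → S; V,E → V; F → F; /,f,Q → Q); non-beat
symbols are ignored, unknown beat symbols fall to Q with a warning.  The
experiments keep N/S/V only: Q dropped, F dropped (well under 0.4 % of
beats), MIT-BIH paced records 102/104/107/217 and record 108 excluded.
Record-level train/test splits are pinned verbatim in
`src/pmat/data/splits.json` (22/21 for mitdb, 39/36 for incartdb, 47
test-only records for edb) and hash-pinned in tests; for the two-hour
European ST-T records, 500 normal beats per record are kept by seeded
uniform subsampling.  Only the MLII lead is used; records without it are
skipped with reason.

The WFDB layer (`pmat.wfdb_io`) is a compact reader/writer for the
header, the 16-bit and packed 12-bit (212) signal formats and the MIT
annotation stream including SKIP/AUX pseudo-annotations.  It is
unit-tested against hand-packed bytes and write/read round-trips.

## Classifier

The image branch is fixed (asserted at construction):
conv 5×5/32 → BN → ReLU → maxpool 5/5 → conv 5×5/64 → BN → ReLU →
maxpool 3/3 → conv 3×3/128 → BN → ReLU → global max pool, producing
128 features with intermediate shapes 116×116×32, 23×23×32, 19×19×64,
6×6×64, 4×4×128, 1×1×128.  The head concatenates the 4 RR features
(132 inputs) and applies dense 132→128→64→3 with ReLU between and a
softmax output.  An optional extra 128→128 dense layer exists behind a
flag, since a four-dense-layer reading of the head is also defensible;
the three-layer head is the default.  Ablations mask one branch:
image-only (input 128) or features-only (input 4, the same dense head
acting as a plain ANN).

Layers are implemented directly on numpy (im2col convolutions backed by
BLAS matmuls, batch normalization with running statistics, argmax-backed
pooling gradients) and each backward pass is verified against finite
differences in the tests.

Training recipe (open design, all configurable): Adam, learning rate
1e-3, batch size 128, 30 epochs, cross-entropy; deterministic given the
seed.  No class weighting by default (optional inverse-frequency
weights behind a flag); RR features enter unstandardized by default
(optional standardization flag).  Ties in the argmax prediction resolve
to the first class in N < S < V order.

## Evaluation

One-vs-rest precision, sensitivity, specificity and F1 from the 3×3
confusion matrix; overall accuracy is trace/total, which reduces to the
binary (TP+TN)/(TP+TN+FP+FN) for two classes and matches
micro-averaged recall.  Macro averages are unweighted class means.  AUC
uses the rank definition (ties count one half) and equals the pairwise
positive-over-negative probability; it is tested against an O(n²)
pairwise oracle.  0/0 ratios are reported as 0 with an `undefined` flag
so degenerate splits still yield macro rows.  Reports render ratios as
percentages to two decimals.

## Synthetic data

Beats are sums of Gaussian bumps (P, Q, R, S, T) with textbook lead-II
proportions; records concatenate beats at jittered RR intervals
(base 0.8 s, 5 % jitter) over a 0.3 Hz sinusoidal drift (amplitude
0.15) plus white noise (s.d. 0.02) at 360 Hz.  Class contrasts give
both classifier branches learnable signal: S beats lack the P wave and
shorten the preceding RR by 30 % (so ratio-RR < 1 by construction);
V beats widen Q/R/S by 1.9× and lack the P wave.  Fixtures are written
as WFDB triplets (gain 1000, keeping 16-bit quantization error under
1e-3 of the signal range).

The end-to-end study in the test suite generates 1,500 beats with the
default 0.8/0.1/0.1 class mix, trains the full model on the first 900
(5 epochs, batch 64 — the synthetic classes separate quickly and this
keeps the study at desk scale) and evaluates on the held-out 598.  It
checks that held-out macro-F1 reaches at least 0.85, that training on
permuted labels collapses to chance level (≤ 0.45), and that the
features-only ablation detects class S well above chance — the
ratio-RR signature carries that class, mirroring the role of timing
features in clinical reading of supraventricular beats.

What this does and does not show: the generator produces cleanly
separable, single-morphology classes from one synthetic "patient"; it
validates the plumbing, the learnability of both branches and the
evaluation stack, but says nothing about inter-patient variability,
real noise, or class imbalance at database scale.  The full-scale
experiments require the real PhysioNet records
(`scripts/reproduce_full.py`).

## Known limitations

* Only formats 16 and 212 of the WFDB signal spec are read; multi-file
  records are not supported.
* Automatic R-peak detection is out of scope: the pipeline relies on
  annotated peaks.
* The CNN is CPU-only; full-database training is hours, not minutes.
* INCART's sampling rate is described inconsistently in the literature
  (275 Hz vs the 257 Hz the public headers declare); the reader always
  trusts the record header.
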