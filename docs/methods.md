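# Methods

## Pipeline model

The package assumes gigapixel (or at least large) RGB rasters of
stained cytology material: dark, roughly blob-shaped nuclear material
on a bright background, with one categorical label per slide. The
processing model is:

1. **Tiling.** Non-overlapping, axis-aligned tiles with a top-left
   origin and 0-based row-major grid coordinates. Big patches are
   1024×1024; each is cut into 16 small patches of 256×256, indexed
   `sp_index = 4·row + col`. Partial border strips are dropped — the
   canonical 1024/256 geometry never produces them, and border slivers
   carry no usable context.
2. **Background filtering.** Grayscale conversion uses ITU-R BT.601
   luma (0.299 R + 0.587 G + 0.114 B), the default of mainstream image
   libraries. Blurring is Gaussian; the kernel parameter follows the
   conventional kernel→sigma mapping σ = 0.3·((k−1)/2 − 1) + 0.8 with a
   footprint radius of (k−1)/2, so `blur_kernel=1` disables smoothing
   entirely (tests that need exact pixel counts pin kernel 1). A pixel
   is "black" (cellular) iff its blurred gray value is ≤ 127. A tile is
   discarded iff its black-pixel fraction is **strictly below** 1%: the
   boundary tile at exactly 1% is retained. Decisions are per-tile and
   deterministic, hence order-independent, and raising the minimum
   ratio can only discard more tiles (monotonicity; both properties are
   tested).
3. **Manual review stand-in.** The expert curation step of a real
   workflow is modeled as a manifest of tile keys to exclude; excluded
   tiles keep their records but are flagged `retained=False`.
4. **Normalization.** uint8 → float via exact division by 255. Tests
   use lossless PNG so oracle comparisons stay bit-exact; JPEG output
   (quality 95) is available for storage parity with common practice.

## Networks

Both networks run on a small numpy engine (`cytomil.nn`) with
hand-derived backward passes. Correctness is established by
finite-difference gradient checks in the test suite; one subtlety is
documented there: checks must use nonzero biases, because with
zero-initialized biases dead upstream ReLU regions place downstream
pre-activations exactly on the ReLU kink, where central differences
measure half-slopes even though the analytic (sub)gradient is the true
one-sided derivative.

**Patch CNN.** Five blocks of 3×3 conv (stride 1, same padding) → ReLU
→ 2×2 max pool (stride 2), then global average pooling, FC(512) → ReLU
→ dropout, FC(256) → ReLU → dropout (this 256-vector is the penultimate
embedding Z), and a linear 4-way softmax head. He initialization
everywhere; L2 (default 1e-4) and dropout (default 0.5) on the FC
layers only. The default channel progression 64→128→256→512→512 is the
conventional doubling scheme inside the 64–512 band where this
architecture is stable; per-layer widths, FC widths, dropout and L2 are
configurable. Argmax ties break to the lowest class index so evaluation
is deterministic.

**Bag classifier.** The same CNN (not pretrained) embeds each of the 16
instances of a bag with shared weights; gated attention
aₙ ∝ exp{wᵀ(tanh(V hₙ) ⊙ σ(U hₙ))} (computed max-shifted) weights the
instances; z = Σ aₙ hₙ feeds a linear softmax head. Defaults: D = 256
(the backbone's penultimate width), attention width L = 128. Zero-padded
slots pass through the extractor and participate in attention exactly
like real instances — the zero image has a well-defined embedding and
the softmax can legitimately down-weight it; an optional `mask_padded`
mode excludes absent slots from the attention softmax for users who
prefer hard masking. The bag embedding is passed directly to the head:
the attention equations produce a single pooled vector, and nothing
else is available to concatenate.

## Training protocol

Weighted cross-entropy with inverse-frequency weights
w_j = M/(N_j·C), used exactly as defined (no rescaling to mean 1); the
identity Σ_j w_j N_j = M is kept as a test. The loss definition is a
sum over samples; the optimizer minimizes the per-batch mean of
per-sample weighted losses for scale stability (the optimum is
unchanged), while `wce_loss` exposes the exact double sum for testing.
Probabilities are clipped to ≥ 1e-7 before the log. Optimization is
Adam, initial learning rate 1e-4, decayed by 0.8 whenever the monitored
validation recall fails to **strictly** improve for 3 consecutive
epochs (the counter resets on decay or improvement). The monitored
recall is macro-averaged over the four classes — micro recall equals
accuracy in single-label multiclass classification and is reported
separately. Canonical protocol: 50 epochs, batch size 8, returned model
= checkpoint with the best validation macro recall. All randomness
(init, shuffling, dropout) derives from explicit seeds; a fixed seed
reproduces a run bit-for-bit on one platform.

## Evaluation conventions

Confusion matrices have true classes in rows. Per-class
precision/recall/F1 are one-vs-rest with the 0/0 → 0 convention; macro
averages are unweighted arithmetic means (this convention reproduces
the published report's Average cells from its per-class cells, which is
how it was validated). ROC and PR curves are per-class one-vs-rest;
AUC is trapezoidal and equal score values are processed as one
threshold step, making AUC equal to the Mann–Whitney pairwise statistic
(tested against a brute-force pair count); AP uses step-wise
precision-weighted recall increments. Stratified splitting defaults to
an 8:2 ratio; patch-level stratification is the default, with a
slide-level granularity option that keeps all tiles of a slide on one
side to prevent leakage in real use. Stratified k-fold delegates to
scikit-learn's `StratifiedKFold`.

## Uncertainty and visualization

For a patch with class probabilities p and penultimate embedding Z:
U_max = −maxᵢ pᵢ ∈ [−1, −1/C]; U_entropy = −Σ pᵢ ln pᵢ ∈ [0, ln C]
(natural log, 0·ln 0 := 0); and the Euclidean norm ‖Z‖ as a salience
proxy. The formulas are implemented as printed in their source even
though the accompanying prose reads U_max in the opposite direction and
calls the entropy negative; the bounds above are the mathematically
correct ones and are property-tested.

Grad-CAM uses the gradient of the target class's **pre-softmax** score
with respect to the final conv block's ReLU output: channel weights are
the spatial means of that gradient, the map is ReLU of the weighted
channel sum, bilinearly upsampled to the patch size and min–max
normalized for display (an all-zero map stays all-zero rather than
dividing by zero). Attention maps place score aₙ at grid cell
(n div 4, n mod 4) and blend a colormap over the reassembled big patch.

## Synthetic data: what it emulates and what it does not

The generator draws dark, stain-colored (luma ≈ 78) blobs on a bright
(gray 245) noisy background, with per-class archetypes:

| class | density/tile | radius (px @256) | irregularity | arrangement |
| --- | --- | --- | --- | --- |
| 0 Nondiagnostic | 10 | 5 ± 1.5 | 0.2 | sparse debris |
| 1 Benign | 25 | 6 ± 1 | 0.1 | loose sheets |
| 2 Follicular neoplasm | 30 | 5 ± 1 | 0.15 | ring-like microfollicles |
| 3 Malignant | 45 | 9 ± 2.5 | 0.6 | large, overlapping, irregular |

Class 0 is sparse but not empty — insufficient-for-diagnosis fields
still contain debris and blood, and a nonzero dark fraction is what
lets some class-0 tiles survive the 1% filter, as they must for the
class to exist downstream. Optional pen-mark artifacts (saturated
strokes) give the exclusion stand-in something to exclude. Every blob
center is returned, so filters, classifiers, attention and heatmaps can
be scored against exact ground truth. Randomness comes from one stream
per call seeded by (seed, category, index), so generation is
bit-reproducible and parallel-safe.

Tiles smaller than 256 px are rendered as **downscaled views of the
same 256-reference field** (same expected blob count, radii and
positions scaled by size/256): a 64 px tile emulates a downsampled
small patch, not a tiny crop, which preserves class signal at reduced
scale and makes density statistics size-invariant.

The generator does **not** emulate stain variation, focus blur, texture
inside nuclei, cytoplasm, or inter-patient variability. Passing tests
therefore demonstrate that the pipeline, losses, attention and
interpretability machinery behave as specified on data with a known,
learnable signal — they say nothing about accuracy on real slides.

## Reduced-scale profiles

Full-scale training (256×256 inputs, 64–512 channels, 274k patches) is
GPU-sized. `cytomil.profiles` defines the CPU-scale study conditions
used by the end-to-end tests:

* **Patch run:** 480 synthetic 64×64 patches (120/class), split 8:2;
  channels (8, 16, 32, 32, 32), FC (64, 32), dropout 0.25; 20 epochs,
  batch 8, initial lr 1e-3. ≈ 40 s on one CPU; validation macro recall
  ≈ 0.98.
* **MIL run:** 96 bags (24/class) of 16 64×64 instances, class-0 bags
  empty and classes 1–3 carrying 4 signal slots; backbone
  (4, 8, 16, 16, 16) with FC (32, 16), attention width 16; 20 epochs,
  batch 8, initial lr 1e-3. ≈ 70 s; trained attention on signal slots
  ≈ 3× that on near-empty slots.

The initial learning rate is 1e-3 here rather than the canonical 1e-4:
the reduced networks and sample sizes train far too slowly at 1e-4,
and the plateau schedule still governs decay. All other protocol
elements are unchanged.

## Known limitations

* The numpy engine is single-threaded apart from BLAS matmuls; it is
  sized for the reduced profiles, not for 256×256 × 274k-patch runs.
* Eq.-level fidelity is to the printed formulas; where prose and
  formula disagree (direction of U_max, sign of the entropy) the
  formula wins and the discrepancy is documented above.
* The bag head consumes the pooled embedding only; if the original
  design concatenated additional inputs, that detail is not recoverable
  from the equations and is not guessed.
* No data augmentation, oversampling, calibration, Monte-Carlo dropout,
  multi-scale fusion, or whole-slide aggregation — class imbalance is
  handled through the loss weights alone, and slide-level diagnosis is
  out of scope.
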