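# Methods

## Scope and study design

The package implements an image-level debiasing pipeline for chest
radiographs (equalization, lung-field segmentation with mask repair and QC,
close cropping, rib suppression), an evolutionary pruning algorithm that
under-samples the majority nodule class, and an ablation harness over the
six operator combinations A–F. All quantitative claims are established on
synthetic phantom radiographs generated by the package itself; the phantom
is a mechanism testbed, not a substitute for clinical data.

## The phantom

Each phantom is composed in normalized [0, 1] floats from separable
additive layers and quantized to 8 bits:

* **Base anatomy** — a bright torso ellipse with a vertical intensity
  gradient (0.80 → 0.52 top to bottom) on a dark background (0.04), with
  two darker elliptical lung fields (interior intensity ×0.42, sharp
  boundary). The ground-truth mask is the exact rasterized ellipse union
  (pixel-center inclusion test, 0-based row/column indices, origin
  top-left). Default geometry at 256 px: centers (138, 82) and (138, 174),
  semi-axes (62, 34), rotations ±0.10 rad, scaled linearly with image size.
* **Ribs** — `rib_count` (7) raised-cosine bands of amplitude
  `rib_amplitude` (0.12) and half-width 0.3 × `rib_period` (26 px), along
  gently drooping sinusoidal paths with per-sample random phase and
  per-rib vertical jitter (σ = 1.5 px), clipped to the torso.
* **Nodule** — one truncated 2-D Gaussian per nodule-class image
  (σ = diameter/4, zero beyond diameter/2; defaults 16 px at contrast
  0.30), centered on a uniformly drawn lung-field pixel.
* **Corner marker** — a fixed 12×24 bright block (+0.35) at the top-left,
  emulating projection labels; present with probability
  `marker_class_correlation` for emitted-nodule images and one minus that
  for controls, so 1.0 makes the marker a perfect class shortcut and 0.5
  makes it independent of class.
* **Site calibration** — per-site `(offset, gain, gamma)` applied to the
  base layer (`base**gamma * gain + offset`) with the additive layers
  scaled by the gain, so the layer decomposition stays exact. Sites are
  assigned round-robin.
* **Label noise** — `round(mislabel_fraction × n_nodule)` of the
  emitted-nodule rows contain no nodule (true label non-nodule). Mislabels
  are planted in the emitted-nodule pool because the pruning algorithm only
  ever removes emitted-nodule rows; recovery of these rows is the
  algorithm's mechanism test.

One RNG stream per dataset is split per-sample by counter
(`SeedSequence((seed, index))`), so any sample can be regenerated alone.

What the phantom does **not** model: patient-to-patient lung size and
position variability, mediastinum/heart silhouette, devices, detector noise
and texture, scatter. Two consequences matter for interpreting results.
First, histogram equalization on the phantom's piecewise-homogeneous
regions amplifies rib contrast much more than on textured clinical images —
which usefully reproduces, in exaggerated form, the observation that ribs
become a dominant confounder after equalization. Second, because lung
geometry is fixed, close cropping has no size variability to normalize;
cropping's external benefit on real data cannot emerge here, and the
harness asserts only that the debiased configurations (D, F) generalize at
least as well as the raw configuration (A), not that F beats D.

## Pipeline operators

Canonical order: **equalize → mask → crop → suppress**. Ablation
configurations toggle inclusion, never order. Equalization is applied once,
before masking, so the black background introduced by segmentation cannot
dominate the histogram; it is not re-applied afterwards.

* *Equalization* is global over `2**bit_depth` bins; the mapping is
  monotone, so pixel ranks are preserved; constant images pass through
  (degenerate CDF guard).
* *Mask repair* pads the mask before the 8×8 closing so the operation is
  truly extensive (output ⊇ input) and idempotent, then fills interior
  holes (4-connectivity) below 1/16 of the image area. The area parameter
  is read as an area in square pixels, not a side length. Foreground
  components use 8-connectivity (the standard dual pairing).
* *Mask QC* fails a mask with fewer than two components, or with a
  second-largest component below 25 % of the largest (a configurable
  "poor visibility" cut; the threshold is a package choice). Failed images
  are dropped from the manifest rather than repaired further.
* *Cropping* takes the minimal bounding box of non-zero pixels; it is
  idempotent and every output border contains content.

## Trained components

No deep-learning framework is assumed; the three trainable slots are filled
with small deterministic numpy learners behind pluggable interfaces, each
trained with an epoch loop, a recorded loss/metric curve, and a fixed seed.

**Segmenter** — per-pixel logistic model over intensity, Gaussian-smoothed
context (σ = 2 and 8) and quadratic coordinate features, trained by
full-batch gradient descent (lr 4.0, 20 epochs, 2000 pixels per image)
with a per-epoch validation Dice curve. Threshold 0.5; ties map to
foreground. Held-out Dice on phantoms is ≈ 0.98; the remaining errors are a
one-pixel boundary band and occasional pinholes at nodules — which is what
the repair operator exists to fix.

**Rib suppressor** — rib bands are thin vertically and long horizontally,
and sit on a positive pedestal. A linear convolution kernel (the obvious
first choice) cannot remove that pedestal: a shift-invariant filter that
preserves the anatomy's DC must pass the bands' DC as well, and the best
learned 33×9 kernel left ≈ 59 % of rib energy. The implemented model
instead computes directional morphological top-hat features — vertical
grey-scale openings at several structuring lengths (12, 18, 24, 32 px)
remove vertically-thin bright structure; a horizontal opening (31 px) of
that residue deletes compact bright features (nodules, corner markers) and
keeps only horizontally-extended bands — and subtracts a linear combination
of those maps. The combination weights are trained by full-batch gradient
descent (MSE against the stored rib layer, standardized features, lr 0.2,
30 epochs, 3000 pixels per image, small non-zero init so the loss always
has head-room). On held-out phantoms the residual rib energy is ≈ 17 % and
nodule peak contrast is preserved within a few percent. Suppressors are
trained per pipeline configuration, on pairs built in the suppressor's
pipeline position (after equalization and any masking/cropping), with one
crop box per pair computed from the rib image.

**Classifier (`tiny_cnn`)** — a fixed convolutional feature extractor and a
trained logistic head. Features per image (resized to 96²): max-pooled
Laplacian-of-Gaussian blob responses at σ = 1.5 and 2.5 over a 4×4 grid,
mean-pooled intensities over the same grid, and four global statistics
(52 features). Blob responses are zeroed where the local 9-px neighborhood
touches near-zero background, so segmentation-mask borders do not drown
genuine blobs; this validity region is derived from the image alone. The
mean-pool and global features deliberately expose corner markers and
brightness offsets — the confounder shortcut must be *learnable* for the
debiasing experiments to mean anything. The head is trained with
binary-cross-entropy by full-batch Adam, 50 epochs at lr 0.1 plus 10
fine-tuning epochs at lr 0.01, L2 0.1, with weights checkpointed at minimum
validation loss. Everything is deterministic given the spec (zero init, no
shuffling). The L2 strength matters for pruning: it must be large enough
that a fold model cannot memorize a planted mislabel it trained on (which
would hide the mislabel from the inference matrix) and small enough that
scores stay sharp around the 0.5 decision cut. The `pretrained_backbone`
architecture id is reserved; the registry accepts user-supplied
classifiers.

## Pruning

Stratified k-fold assignment (k = 4, scikit-learn `StratifiedKFold`,
shuffled, seeded) is fixed at round 0 and reused; pruned images simply drop
out. Each round retrains the k fold models from scratch (seed schedule
`seed + round`), checkpoints each at minimum validation loss, computes each
model's score for every active nodule image, and replicates the k scores
k-fold — one per shard context — giving exactly k² bookkept inferences per
image; a misclassification is a score below the 0.5 decision threshold.
The image with the largest misclassification count is pruned; ties break by
lowest mean score, then lexicographically smallest image id. The loop stops
at class balance (154 → 93 takes exactly 61 rounds) or at `max_rounds`.
After stopping, one extra fold-model evaluation on the balanced manifest
records the AUC at the stopping point. AUC is rank-based with ties credited
0.5; the per-round spread is reported as the sample standard deviation
(ddof 1) over the k folds. The "stable AUC" round is the first round from
which the mean AUC stays at or above the target (default 0.80) for a
3-round window; the window truncates at the ledger end only if every
remaining round qualifies.

## Ablation and external testing

`expand_grid()` yields the six configurations (segmentation, cropping,
suppression): A (F,F,F), B (F,F,T), C (T,F,F), D (T,F,T), E (T,T,F),
F (T,T,T); cropping is only valid with segmentation. `run_experiment`
preprocesses the corpus (QC failures dropped), runs the pruning loop to
balance, and trains a master model on the balanced set with a stratified
20 % holdout used only for checkpoint selection. `external_inference`
applies the byte-identical configuration (asserted via a config hash,
including the same trained suppressor) to a positives-only external corpus
and reports the fraction of nodule probabilities above 0.5.

Study conditions for the debiasing experiments: training corpus of 36
emitted-nodule / 30 control phantoms with the corner marker perfectly
correlated with class (marker_class_correlation = 1.0, consistent with
projection labels being near-perfect source predictors) and two site
profiles (−0.04, 0.95, 1.10) and (0.05, 1.08, 0.90) assigned round-robin;
external corpus of 24 nodule-only phantoms from an unseen site
(0.08, 1.15, 0.85) with no markers. Under these conditions the raw model
(A) learns the marker shortcut and collapses externally (accuracy ≈ 0 at
the 0.5 cut), while the debiased pipelines, which excise the marker by
masking and cropping, transfer their nodule detector.

## Desk-scale problem sizes

Test-suite and acceptance runs use: 247-image corpora for the pruning
bookkeeping (154/93, 61 rounds, under a minute), 44-image corpora with 4
planted mislabels over 5 seeds for recovery, 66-train/24-external corpora
over 5 seeds for the debiasing ordering, 64/16 train/held-out splits for
the segmenter and suppressor. These sizes were chosen so each mechanism is
measured with enough replication to be stable while the whole study remains
a desk-scale computation.

## Known limitations

* Phantom realism limits (above): no anatomy variability, no noise model;
  passing tests demonstrate the pipeline's mechanisms, not clinical
  performance.
* The suppressor's structuring-element lengths assume rib bands thinner
  than ~32 px and nodules narrower than ~31 px at native resolution; very
  large nodules would be partially suppressed.
* The segmenter's coordinate features tie it to roughly centered lung
  fields; it is a phantom-scale stand-in for a full segmentation network,
  pluggable behind `predict_proba_map`.
* Mask QC's visibility ratio (0.25) is a package constant; the literature
  gives no number.
* External accuracy on an all-positive corpus is threshold-sensitive by
  construction; it is reported at the 0.5 cut only.
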