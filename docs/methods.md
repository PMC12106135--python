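# Methods

This note documents the models, conventions and design choices behind
`hemaseg`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the genuinely open choices were resolved.

## CT representation and preprocessing

A scan is a stack of axial slices stored as integer DICOM values; Hounsfield
units are recovered with the linear rescale `x_HU = x·slope + intercept`
from the per-file header. Contrast windowing maps an HU interval
`[lower, upper]` onto [0, 255] piecewise-linearly (saturating outside);
the default window is [0, 140] HU, wide enough to keep both brain tissue
(~30 HU) and acute blood (~50–90 HU) on-scale while discarding bone and
air. Values stay floating point through the pipeline; quantisation to
uint8 happens only on export, avoiding double rounding before
normalisation.

Head orientation is estimated without any learned component: the HU volume
is thresholded (default 100 HU, which keeps skull), each slice's largest
connected component is reduced to its second-order image moments, and the
median over slices of the principal-axis angle (relative to the vertical
image axis, counter-clockwise positive, range (−90°, 90°]) is taken. The
correcting rotation (−angle about the image centre) is applied bilinearly
to the image and nearest-neighbour to masks so masks stay binary. Size
standardisation zero-pads smaller slices symmetrically — the odd extra
pixel goes to the bottom/right — and centre-crops larger ones, with the odd
extra pixel removed bottom/right; both conventions are pinned so geometric
tests can be bit-exact. Min–max normalisation maps a constant slice to all
zeros ("no information") rather than dividing by zero.

Pipeline order is HU → window → orient → size → normalise. Training-time
augmentation (horizontal flip, rotation ±15°, zoom 0.9–1.1, shift ±10%,
brightness/contrast jitter ±20%, each firing independently with
probability 0.5) is fully seeded; geometric transforms hit image and mask
identically, photometric jitter hits the image only.

## Model

The architecture follows the promptable-segmentation design: a ViT image
encoder, a sparse prompt encoder, and a two-way cross-attention mask
decoder.

* **Encoder.** Non-overlapping patches are linearly embedded, given a
  learned positional embedding, and passed through pre-norm transformer
  blocks. Blocks listed in `global_attn_indices` attend globally; the
  rest use non-overlapping local window attention (window = token-grid
  side / 4 for the ViT-B preset). The tiny preset (image 64, patch 8,
  d = 64, depth 4, all-global) is the workhorse for CPU-scale experiments;
  the `vit_b` preset (image 1024, patch 16, d = 768, depth 12, four global
  blocks) exists chiefly so the parameter accounting matches the full-size
  model. Residual-branch output projections are initialised with an extra
  1/√(2·depth) factor, which keeps the residual stream near unit variance
  and makes from-scratch training of the tiny preset stable at standard
  AdamW rates.
* **Adapters.** One bottleneck adapter
  (`W_up ReLU(W_down x + b_down) + b_up + x`) after the attention
  sub-layer and one after the MLP sub-layer of each block. `W_up` is
  zero-initialised, so a freshly adapted model is *exactly* the frozen
  backbone — a property the tests assert bitwise. Biases are included by
  default (both variants satisfy the <4M budget) and can be disabled.
  Default bottleneck m = 100 for ViT-B (the best-performing dimension in
  the underlying experiments); m = 8 for the tiny preset, keeping the same
  d/m ratio regime.
* **Prompts.** Points and boxes are encoded with a random-Fourier
  positional code plus a learned per-type embedding; one token per point,
  two corner tokens per box, a learned padding token when no prompt is
  given. The training/inference prompt protocol is not externally fixed,
  so the default is the fully automatic one: a whole-image box for both
  training and inference (train/test conditions match). A
  ground-truth-bounding-box mode (`prompt_mode="gt_box"`, dilated by a
  configurable margin) is available for prompted evaluation.
* **Decoder.** Two two-way blocks (token self-attention, token→image and
  image→token cross-attention), a learned per-token upscaling of the image
  embedding (factor 4, then nearest-neighbour to input resolution), and a
  hypernetwork MLP that turns the mask token into a dynamic linear
  classifier over the upscaled features. The hypernetwork's last layer is
  near-zero-initialised and a learned scalar logit bias starts at −3, so
  an untrained model predicts background everywhere — segmentation
  training then grows the foreground, which is far more stable than
  shrinking random speckle. A single mask output is produced (binary
  task; no multimask ambiguity head).
* **Freezing.** `adapters_only` (default for fine-tuning; honours the
  <4M-parameter claim), `adapters_plus_decoder` (adapters + mask decoder +
  prompt encoder — the sensible setting when the decoder is trained from
  random initialisation, as in the phantom experiments), and `full`.
  The optimizer skips frozen parameters entirely, so they are bit-identical
  across any number of steps.

Because no deep-learning framework is assumed, the model runs on a compact
reverse-mode autodiff engine over float64 numpy arrays
(`hemaseg.autodiff`): broadcasting arithmetic, batched matmul, fused
softmax/LayerNorm/GELU primitives, reductions, indexing, and a decoupled
weight-decay Adam. All gradients are covered by central finite-difference
tests.

## Losses

* BCE (mean pixelwise cross-entropy). The training loop evaluates it in
  logit space (`mean(softplus(x) − x·y)`); the probability-space form
  loses its gradient to clamping once logits saturate.
* Soft Dice: `1 − (2Σpy + s)/(Σp + Σy + s)`, smooth s = 1 by default.
* Focal Tversky: `TI = (TP+ε)/(TP + α·FP + (1−α)·FN + ε)` with soft
  counts, loss `(1 − TI)^γ`; defaults α = 0.4, γ = 1, ε = 0.01. TI is
  clamped to [1e−6, 1−1e−6] before exponentiation — the focal form is
  otherwise prone to exploding gradients when the index saturates, and a
  non-finite loss aborts training with a diagnostic rather than silently
  corrupting weights. The β = 1−α convention and the placement of ε in
  numerator and denominator are pinned here for reproducibility; with
  γ = 1 the alternatives coincide.
* Boundary loss: the distance-map surface loss `mean(sdm·p)` against the
  ground truth's signed Euclidean distance map (negative inside, zero on
  boundary pixels — mask pixels with a 4-neighbour background — positive
  outside). Degenerate all-empty/all-full masks get a uniform ±(image
  diagonal) map with a warning, keeping the loss finite on negative
  slices. No epoch ramp of the boundary weight is applied.
* Combinations: printed-percentage weights (e.g. `bce:0.5,boundary:0.5`)
  are normalised to sum to 1.

## Metrics and aggregation

Dice, IoU and VS are computed on voxel counts (2-D or 3-D); when
prediction and reference are both empty the overlap scores are 1 — an
empty prediction on a negative slice is a correct answer — and undefined
confusion ratios return 1 with a `*_defined` flag. This convention
materially affects slice-level means on negative-slice-rich cohorts, so it
is explicit and localised. The 95%HD pools both directed boundary
nearest-neighbour distance sets and takes the linear-interpolation
percentile; percentile 100 recovers the classical Hausdorff maximum.
Boundary pixels use 4-connectivity (6 in 3-D, out-of-grid counts as
background); distances are in pixels unless a spacing is attached. Slices
with an empty mask on either side have an undefined 95%HD; they are
excluded from aggregation with a logged count. Fold aggregation reports
mean-of-fold-means ± sd-of-fold-means at slice level and
mean-of-fold-means ± mean-of-fold-sds at scan level, with the sample
(n−1) standard deviation throughout.

## Experimental protocol

Scans are split 20% test / 5-fold cross-validation on the rest, stratified
by scan positivity: per stratum, ids are shuffled deterministically, a
proportional share is held out, and the remainder is dealt round-robin
with a rolling fold offset so fold sizes and class ratios stay balanced.
Training iterates all training slices (negatives included) in a per-epoch
shuffled order, AdamW with weight decay 0.1 and batch size 2; the 5e-5
default learning rate is the fine-tuning rate appropriate to a pretrained
backbone. The desk-scale phantom experiments train a randomly initialised
tiny model from scratch, where 1e-3 — the standard AdamW rate for small
models — is used instead; "decay rate 0.1" is interpreted as AdamW weight
decay (no learning-rate schedule). The final-epoch checkpoint is kept.
Checkpoints are flat name→array `.npz` archives and restore bit-identically;
initialising from a checkpoint supports the pretrain-then-finetune
workflow (pretraining emulated with a phantom cohort).

Model comparison: per-scan scores form an n-blocks × k-models matrix;
Friedman's test uses within-block average ranks and
`χ²_F = 12/(nk(k+1))·ΣR_j² − 3n(k+1)` against χ²(k−1) (no tie
correction — ties are averaged in the ranks). The Nemenyi post-hoc flags
pairs whose mean-rank difference exceeds
`CD = q_{α,k}·√(k(k+1)/6n)`, with q tabulated for k ≤ 10 at α ∈ {0.05,
0.10} (two-sided studentized range / √2, infinite df); it refuses to run
without a significant omnibus test unless forced. Bootstrap CIs are
percentile bootstraps over scans.

## Synthetic phantoms

Each phantom slice holds an elliptical skull ring (~900 HU), brain tissue
(30 HU) and, on positive scans, one or two lesions: thresholded sums of
2–4 overlapping Gaussians (irregular but smooth blobs) painted at a
per-lesion HU drawn from 50–90, spanning a contiguous slice range with a
parabolic area profile. Gaussian noise (sd 3 HU) is added after masks are
fixed, so ground truth is exact. Stored values encode HU through slope 1
and a per-scan intercept drawn from [−1100, −950], exercising the rescale
transform nontrivially; written DICOM series are deterministic (seeded
UIDs, no timestamps) and round-trip bit-exactly. Default cohort scale
(12–15 scans of 4–7 slices at 64×64) is chosen so a full pipeline run
takes tens of seconds on one CPU; lesion areas (60–400 px) occupy a
realistic few percent of the slice.

The simulated second annotator shifts and dilates/erodes each lesion
component by a few pixels (magnitude `annotator_perturb_px`) and misses
small lesions with a configurable rate — a fixed-absolute-error model of
human boundary disagreement. Because the error is fixed in pixels,
relative overlap degrades fastest on small lesions, reproducing the
observed size dependence of inter-reviewer agreement; agreement is exact
at zero perturbation and decreases monotonically in the magnitude.

What the phantoms do *not* model: real brain anatomy, skull-base and
posterior-fossa artefacts, beam hardening, partial-volume effects,
hematoma subtypes, or annotator biases that correlate across readers.
Passing the phantom suites therefore demonstrates the correctness and
determinism of the machinery — preprocessing, optimisation, metrics,
statistics — not clinical-grade segmentation accuracy; cohort-level scores
on patient data are explicitly out of scope.

## Pipeline and reproducibility

The staged pipeline (simulate → preprocess → split → train → evaluate →
compare → agreement) reads every constant from one YAML-serialisable
config; artifacts carry a config hash that changes iff any constant
changes. All randomness derives from one global seed through named,
hash-separated substreams, so stages are individually resumable and two
runs from the same config and seed produce byte-identical metric CSVs,
checkpoints and DICOM files. Default desk-scale settings (15 scans,
3 folds, 6 epochs, three loss variants) keep a full run under ~20 s;
the 3-fold choice at this cohort size keeps every stratum large enough
for stratified folding.

## Known limitations

2-D slice-level segmentation only (no volumetric context); the ViT-B
preset is built for parameter accounting and weight-loading, not for
CPU training; the autodiff engine is float64 and single-threaded by
design, trading speed for exact reproducibility; the Nemenyi table covers
k ≤ 10 models; phantom realism as above.
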