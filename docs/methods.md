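# Methods

## Problem and model

Grading pod rot severity of a peanut plant from an RGB image decomposes into
object detection (find every pod, classify it non-rotted `G` / rotten `R`)
followed by deterministic arithmetic (rotten pod rate, ordinal grade). The
detector is a single-stage anchor-based model in the CSPDarknet family:
a backbone of strided convolutions and C3 (cross-stage-partial bottleneck)
blocks ending in SPPF pooling, a top-down + bottom-up fusion neck, and a
coupled 1×1-conv prediction head at strides 8/16/32 with three anchors per
scale and `3 × (5 + 2)` output channels per cell. Two deltas define the
improved variant ("es"):

* **Shuffle attention after each backbone C3.** Channels are split into `G`
  groups; each group is halved into a channel branch (sigmoid gate on the
  globally average-pooled response) and a spatial branch (sigmoid gate on the
  group-normalized map); the halves are re-concatenated and mixed by a
  channel shuffle with `G` groups. Insertion sites are the backbone C3 stages
  only — the neck is untouched. Each site adds exactly four affine vectors of
  length `C/(2G)` per group, i.e. `2C` parameters; the group-norm carries no
  separate affine pair (its scale/shift are the gate parameters). The model
  asserts this census against the analytic formula.
* **EIoU localization loss.** `1 − IoU + ρ²/c² + (w−w^gt)²/c_w² +
  (h−h^gt)²/c_h²`, replacing CIoU's aspect-ratio surrogate `αv` with explicit
  width/height differences normalized by the enclosing rectangle. CIoU
  remains selectable for ablations; its piecewise weight `α` is zero below
  IoU 0.5 and `v/(1 − IoU + v)` above, and is treated as a constant during
  backpropagation (the usual practice). A focal variant `IoU^γ · EIoU` is
  implemented and off by default (γ = 0): the provenance of the focal
  weighting in this design is ambiguous between the classification and
  localization sides, so the localization-side form from the EIoU literature
  is provided without being wired into training.

The total loss is the unweighted sum of classification, localization and
confidence terms (per-component weights are config-exposed and default to
the conventional 0.5 / 0.05 / 1.0 multipliers inside the trainer; the
`LossBreakdown` sum identity is over the weighted parts). Objectness targets
use the detached prediction–truth IoU; classification and objectness use
binary cross-entropy. Assignment follows the anchor-ratio rule (`max(r, 1/r)
< 4` on both axes) at the cell containing the truth center; neighbor-cell
assignment is deliberately omitted at this scale.

## Numerical backbone

No GPU framework is used: the package carries a compact reverse-mode
autograd engine over float32 numpy arrays (im2col convolution, max pooling,
nearest upsampling, broadcasted arithmetic, reductions, slicing). Batch norm
uses batch statistics in training mode and running estimates (momentum 0.1,
eps 1e−5) in evaluation; group norm in the attention branch uses eps 1e−5.
Adam (β = 0.9/0.999, eps 1e−8) performs updates. Denominators in the box
losses carry an epsilon of 1e−7–1e−9 only away from coincidence; identical
boxes short-circuit to zero because the ratio terms are 0/0 there.

Two detector sizes exist from the same stage machinery: the small variant
(width ×0.5, depth ×0.33, 640×640 input, stock anchors, SA groups 16) and a
tiny variant for CPU smoke training (width ×0.125, one bottleneck per C3,
160×160 input, SA groups 4 so the smallest width of 16 channels still splits
into 2×4 groups). The stock pixel anchors are kept at all input sizes; the
synthetic pods (10–30 px after letterboxing) match the stride-8/16 anchors.

## Grading

Rotten pod rate `= R/(G + R)`; the five-level scale is right-closed at its
knots: rate 0 → level 1, (0, 0.10] → 3, (0.10, 0.25] → 5, (0.25, 0.50] → 7,
(0.50, 1] → 9. The prose definition of the scale is ambiguous exactly at the
knots; right-closed intervals make "larger than 50 %" exact and are applied
uniformly. An image with no detections has an undefined rate (0/0); it is
recorded as level 1 with rate 0 and an `empty` flag rather than failing a
batch run. The aggregate report places non-rotted count, rotten count,
total, rate and grade in columns 2–6 after the image id; the total in
column 4 is an inferred layout choice (the source layout names columns 2, 3,
5 and 6 only). The spreadsheet is mirrored to CSV for diffability.

## Evaluation

Matching is greedy per class: predictions in descending confidence claim the
highest-IoU unclaimed truth at IoU ≥ 0.5 (the family-default threshold; the
source does not state one). AP uses 101-point recall interpolation
(config-selectable to all-point); mAP is the two-class mean × 100.
Comparison Precision counts an image as correct only with zero FP and zero
FN across both classes — the strictest reading of "correctly identifies",
consistent with treating missed pods and duplicate boxes as failures — and
is rounded half-up to two decimals to match the printed precision of the
published tallies. A seeded five-fold splitter supports cross-validation
runs.

## Synthetic scenes

The generator emulates the study imagery only as far as the pipeline needs:
two visually distinct pod classes (tan speckled vs dark mottled ellipses),
curvilinear distractor strokes sharing the rotten palette (the real
confound: rotten pods resemble rotten roots/stems), and three adhesion
strata defined on pairwise ground-truth box IoU — none (all 0), slight (max
in (0, 0.3]), severe (some pair > 0.3). The 0.3 knot is an artifact-defined
operationalization of a visual judgment, config-exposed. Placement is
rejection sampling with a bounded deterministic fallback that plants one
canonical overlapping pair; generation is byte-deterministic given the seed.
Defaults (8–12 pods per scene, rotten fraction 0.3, 320×320 canvas) give
per-image rates spanning all five grade levels. What passing tests show:
the pipeline's bookkeeping, losses, metrics and training dynamics are
correct on imagery whose statistics it controls. What they do not show:
performance on real field imagery — lighting, soil variation, true pod
morphology and label noise are all absent, so the published accuracy figures
are not reproducible here and are not claimed.

## Scale of the shipped experiments

The smoke experiments are sized for a single CPU: ~80 synthetic scenes
letterboxed to 160 px, tiny variant, ≤ 20 epochs, batch 8 — enough for
held-out mAP to rise decisively above the untrained model. The ablation grid
(± attention × CIoU/EIoU) runs 4 trainings at 128 px for a handful of
epochs; at that scale the grid demonstrates the machinery (shared split,
independent toggles), not stable rankings. The reference configuration
(200 epochs, batch 32, lr 0.01, 2 classes) remains the config default for
full-scale runs.

## Known limitations

* The engine is single-threaded numpy; full-scale (640 px, width 0.5)
  training is out of scope, inference at that size takes seconds per image.
* The prediction head is the stock coupled head; a decoupled head is
  described ambiguously in the source material and was not adopted.
* Rotation augmentation replaces boxes by the axis-aligned bounds of rotated
  corners, which inflates boxes slightly at large angles (bounded by the
  ±15° default).
* The rotten *kernel* rate (decay confined to the shell vs the kernel) is
  outside the model; grading is by pod appearance only.
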